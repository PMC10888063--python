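import numpy as np
import pandas as pd
import pytest

from cadi.synthetic import ScenarioConfig, gen_corpus, make_vocabulary
from cadi.pod import PODBuilder


@pytest.fixture(scope="session")
def tiny_config():
    """A small but fully featured scenario used across module tests."""
    return ScenarioConfig(n_regions=6, years=(2018, 2020), n_words=10,
                          n_docs=300, noise_sd=0.1, seed=3, trend_freq="MS")


@pytest.fixture(scope="session")
def planted_corpus_config():
    return ScenarioConfig(n_regions=2, n_words=20, n_docs=1200,
                          cooccur_excess=0.8, seed=7)


@pytest.fixture(scope="session")
def planted_corpus(planted_corpus_config):
    return gen_corpus(planted_corpus_config)


@pytest.fixture(scope="session")
def planted_vocab(planted_corpus_config):
    return make_vocabulary(planted_corpus_config)


@pytest.fixture(scope="session")
def fitted_pod_builder(planted_corpus):
    """One CBOW training shared by the dictionary-quality tests."""
    return PODBuilder(dim=50, epochs=8, min_frequency=5, seed=7).fit(
        planted_corpus)


def random_balanced_panel(rng, regions=8, words=10, years=(2018, 2019, 2020)):
    """A random balanced (region, word, year, gamma_bar) panel plus weights."""
    region_names = [f"R{i:02d}" for i in range(regions)]
    word_names = [f"w{i:02d}" for i in range(words)]
    rows = []
    for y in years:
        for r in region_names:
            for w in word_names:
                rows.append((r, w, y, rng.uniform(0.0, 10.0)))
    panel = pd.DataFrame(rows, columns=["region", "word", "year", "gamma_bar"])
    wrows = []
    for y in years:
        raw = rng.uniform(0.1, 1.0, words)
        wnorm = raw / raw.sum()
        for w, ww in zip(word_names, wnorm):
            wrows.append((w, y, ww, ww))
    weights = pd.DataFrame(wrows, columns=["word", "year", "phi", "w"])
    return panel, weights


def cadi_oracle(panel, weights, tau):
    """Naive triple-loop recomputation of the index, kept deliberately dumb."""
    out = {}
    wmap = {(w, y): v for w, y, v in
            weights[["word", "year", "w"]].itertuples(index=False)}
    for (region, year) in {(r, y) for r, y in
                           panel[["region", "year"]].itertuples(index=False)}:
        total = 0.0
        for word in weights.loc[weights["year"] == year, "word"]:
            cell = panel[(panel["word"] == word) & (panel["year"] == year)]
            vals = cell["gamma_bar"].tolist()
            lo, hi = min(vals), max(vals)
            v = cell.loc[cell["region"] == region, "gamma_bar"].iloc[0]
            frac = 0.5 if hi == lo else (v - lo) / (hi - lo)
            total += (frac * tau + (100.0 - tau)) * wmap[(word, year)]
        out[(region, year)] = total
    return out
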