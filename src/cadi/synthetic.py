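"""Synthetic study generator with a planted latent severity signal.

Emulates every input stream the index pipeline consumes — an emotion-rich
tagged text corpus, regional and national search-trend series, populations,
an Internet-penetration series, a regional covariate panel and survey
microdata — from one :class:`ScenarioConfig`. A single latent variable
``s(region, year)`` ("negative mental-health severity", higher = worse) ties
the streams together:

* covariates generate ``s`` linearly (default: IE loads negatively, ACP
  positively, all other effects zero),
* each word's regional search trend rises with ``s`` in proportion to the
  word's true relevance,
* survey respondents report a mental disorder with probability increasing
  in their region's ``s``.

Because the planted structure is known, rank-recovery and sign-recovery of
the downstream index and regressions are assertable. Everything is
deterministic under the config seed; each stream draws from its own
seed-derived substream so generators can be called in any order.

The default scenario mirrors the study scale the pipeline targets: 31
regions observed over 2016-2021.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "COVARIATE_NAMES", "TARGET_WORDS", "ScenarioConfig", "VocabularySpec",
    "make_vocabulary", "gen_corpus", "gen_trend_panel",
    "gen_population_penetration", "gen_covariates", "gen_survey",
    "gen_covariates_survey", "simulate_scenario",
]

COVARIATE_NAMES = ("DI", "CPI", "CGR", "IE", "ACP", "RHE", "RD", "RU")
TARGET_WORDS = ("anxiety", "depression")

#: context window used when planting word/target co-occurrences
COOCCUR_WINDOW = 5

# substream ids so each generator has its own independent RNG
_STREAM_CORPUS, _STREAM_TRENDS, _STREAM_POP, _STREAM_COV, _STREAM_SURVEY = range(5)


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    ``years`` is an inclusive (first, last) range. ``noise_sd`` is the
    standard deviation of both the trend observation noise and the residual
    in the latent-severity equation. ``effect_sizes`` maps covariate names
    to the signed linear effects that generate severity.
    """

    n_regions: int = 31
    years: Tuple[int, int] = (2016, 2021)
    n_words: int = 20
    n_docs: int = 2000
    noise_sd: float = 0.1
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"IE": -1.0, "ACP": 1.0})
    seed: int = 0

    # corpus conditions
    planted_frac: float = 0.3
    cooccur_excess: float = 0.8
    emotional_doc_rate: float = 0.5

    # trend conditions
    lam: float = 1.0                       # severity loading on trends
    trend_freq: str = "D"                  # pandas offset alias: D, MS, YS
    base_trend_range: Tuple[float, float] = (20.0, 80.0)
    relevance_planted: float = 0.8
    relevance_background: float = 0.05

    # population / penetration conditions
    population_base: float = 4.5e7
    population_growth: float = 0.002
    penetration_start: float = 0.50
    penetration_growth: float = 0.05

    # survey conditions
    survey_year: int = 2020
    survey_n_per_region: int = 200
    survey_base_prevalence: float = 0.12
    survey_slope: float = 1.0

    def __post_init__(self):
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError(f"empty year range {self.years}")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2 (min-max scaling "
                             "needs at least two regions)")
        if self.n_words < 1:
            raise ValueError("n_words must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        unknown = set(self.effect_sizes) - set(COVARIATE_NAMES)
        if unknown:
            raise ValueError(
                f"unknown covariate name(s) in effect_sizes: {sorted(unknown)}; "
                f"valid names: {list(COVARIATE_NAMES)}")

    @property
    def year_list(self) -> list:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def effective_survey_year(self) -> int:
        """The survey year clipped into the scenario's year span."""
        return int(min(max(self.survey_year, self.years[0]), self.years[1]))

    @property
    def region_names(self) -> list:
        return [f"R{i:02d}" for i in range(1, self.n_regions + 1)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(d["years"])
        d["effect_sizes"] = dict(d["effect_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(d["years"])
        for key in ("base_trend_range",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class VocabularySpec:
    """Token universe: targets, planted-relevant words, background words.

    ``fillers`` are extra non-content tokens (verbs, adverbs, a one-character
    noun) that exercise the POS and length filters downstream; they never
    enter the trend panel.
    """

    targets: list
    planted: list
    background: list
    fillers: list  # (surface, pos) pairs

    @property
    def content_words(self) -> list:
        return self.planted + self.background

    def pos_of(self, word: str) -> str:
        if word in self.targets:
            return "n"
        pool = self.content_words
        if word in pool:
            return "n" if pool.index(word) % 2 == 0 else "a"
        for surface, pos in self.fillers:
            if surface == word:
                return pos
        raise KeyError(word)


def make_vocabulary(config: ScenarioConfig) -> VocabularySpec:
    n_planted = max(1, round(config.planted_frac * config.n_words))
    n_planted = min(n_planted, config.n_words)
    planted = [f"planted{i:02d}" for i in range(n_planted)]
    background = [f"bg{i:02d}" for i in range(config.n_words - n_planted)]
    fillers = [("doing00", "v"), ("doing01", "v"), ("doing02", "v"),
               ("now00", "d"), ("now01", "d"), ("q", "n")]
    return VocabularySpec(targets=list(TARGET_WORDS), planted=planted,
                          background=background, fillers=fillers)


def _tag(vocab: VocabularySpec, word: str) -> str:
    return f"{word}/{vocab.pos_of(word)}"


def gen_corpus(config: ScenarioConfig) -> pd.DataFrame:
    """Generate the tagged pseudo-text corpus.

    Each document is a whitespace-joined sequence of ``surface/POS`` tokens.
    Planted-relevant words are inserted adjacent to target-word occurrences
    at rate ``cooccur_excess`` on top of their chance appearance rate;
    background words co-occur with targets at chance only. Document
    character counts (sum of surface lengths) span both sides of the
    15-character screening threshold.
    """
    if config.n_docs == 0:
        raise ValueError("n_docs is 0: cannot generate an empty corpus")
    rng = config.rng(_STREAM_CORPUS)
    vocab = make_vocabulary(config)
    content = vocab.content_words
    filler_surfaces = [s for s, _ in vocab.fillers]
    platforms = np.array(["weibo", "douban", "zhihu"])
    dates = pd.date_range("2020-01-01", "2020-06-30", freq="D")

    rows = []
    for d in range(config.n_docs):
        n_tokens = int(rng.integers(1, 16))
        emotional = rng.random() < config.emotional_doc_rate
        # emotional documents skew their content toward planted words in
        # proportion to the excess rate; at excess 0 every document draws
        # uniformly and planted words are indistinguishable from background
        planted_rate = 0.5 * config.cooccur_excess if emotional else 0.0
        tokens = []
        for _ in range(n_tokens):
            u = rng.random()
            if u < 0.15:
                tokens.append(filler_surfaces[int(rng.integers(len(filler_surfaces)))])
            elif rng.random() < planted_rate:
                tokens.append(vocab.planted[int(rng.integers(len(vocab.planted)))])
            else:
                tokens.append(content[int(rng.integers(len(content)))])
        if emotional:
            n_targets = int(rng.integers(1, 3))
            for _ in range(n_targets):
                t_word = vocab.targets[int(rng.integers(len(vocab.targets)))]
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens.insert(pos, t_word)
                if rng.random() < config.cooccur_excess:
                    p_word = vocab.planted[int(rng.integers(len(vocab.planted)))]
                    side = int(rng.integers(0, 2))
                    tokens.insert(pos + side, p_word)
        text = " ".join(_tag(vocab, w) for w in tokens)
        rows.append((f"doc{d:05d}",
                     platforms[int(rng.integers(3))],
                     dates[int(rng.integers(len(dates)))].date().isoformat(),
                     text))
    return pd.DataFrame(rows, columns=["id", "platform", "date", "text"])


def true_relevance(config: ScenarioConfig) -> pd.DataFrame:
    """The generator's ground-truth word relevance (word, relevance)."""
    vocab = make_vocabulary(config)
    rows = ([(w, config.relevance_planted) for w in vocab.planted]
            + [(w, config.relevance_background) for w in vocab.background])
    return pd.DataFrame(rows, columns=["word", "relevance"])


def gen_trend_panel(config: ScenarioConfig, severity: pd.DataFrame,
                    relevance: Mapping[str, float],
                    populations: Optional[pd.DataFrame] = None,
                    freq: Optional[str] = None) -> pd.DataFrame:
    """Generate regional + national search-trend series.

    The regional trend of word i at time t in region r is

        base(i) + lam * s(r, year(t)) * relevance(i) + N(0, noise_sd),

    truncated at zero. The national series is the population-weighted mean
    of the regional series (plain mean when no populations are supplied).
    Output is long format (region, word, date, value) with national rows
    labelled ``NATIONAL``.
    """
    if severity is None or len(severity) == 0:
        raise ValueError("severity table is empty; generate covariates first")
    rel = pd.Series(dict(relevance), dtype=float)
    if ((rel < 0) | (rel > 1)).any():
        raise ValueError("relevance values must lie in [0, 1]")
    rng = config.rng(_STREAM_TRENDS)
    words = list(rel.index)
    regions = sorted(severity["region"].astype(str).unique())
    freq = freq or config.trend_freq
    y0, y1 = severity["year"].min(), severity["year"].max()
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq=freq)
    date_years = dates.year.values

    s_tab = severity.pivot_table(index="region", columns="year", values="s",
                                 aggfunc="first").reindex(regions)
    s_by_date = s_tab[date_years].values                    # (R, T)

    lo, hi = config.base_trend_range
    base = rng.uniform(lo, hi, size=len(words))
    rel_v = rel.values
    signal = (base[None, :, None]
              + config.lam * s_by_date[:, None, :] * rel_v[None, :, None])
    noise = (rng.normal(0.0, config.noise_sd, size=signal.shape)
             if config.noise_sd > 0 else 0.0)
    values = np.maximum(signal + noise, 0.0)                # (R, W, T)

    if populations is not None:
        pop = populations.pivot_table(index="region", columns="year",
                                      values="population",
                                      aggfunc="first").reindex(regions)
        wts = pop[date_years].values                        # (R, T)
    else:
        wts = np.ones((len(regions), len(dates)))
    national = ((values * wts[:, None, :]).sum(axis=0)
                / wts.sum(axis=0)[None, :])                 # (W, T)

    R, W, T = values.shape
    date_str = dates.strftime("%Y-%m-%d")
    frame = pd.DataFrame({
        "region": np.repeat(regions, W * T),
        "word": np.tile(np.repeat(words, T), R),
        "date": np.tile(date_str, R * W),
        "value": values.reshape(-1),
    })
    nat = pd.DataFrame({
        "region": "NATIONAL",
        "word": np.repeat(words, T),
        "date": np.tile(date_str, W),
        "value": national.reshape(-1),
    })
    return pd.concat([frame, nat], ignore_index=True)


def gen_population_penetration(config: ScenarioConfig,
                               constant_penetration: bool = False,
                               heterogeneity: float = 0.0):
    """Generate the population table and the penetration series.

    Populations default to being equal across regions within each year
    (growing slowly over years); ``heterogeneity`` > 0 multiplies each
    region by a fixed lognormal factor instead. Penetration grows at
    ``penetration_growth`` per year from ``penetration_start`` unless
    ``constant_penetration`` is set.
    """
    rng = config.rng(_STREAM_POP)
    years = config.year_list
    regions = config.region_names
    region_factor = (np.exp(rng.normal(0.0, heterogeneity, len(regions)))
                     if heterogeneity > 0 else np.ones(len(regions)))
    rows = []
    for j, y in enumerate(years):
        base = config.population_base * (1.0 + config.population_growth) ** j
        for i, r in enumerate(regions):
            rows.append((r, y, base * region_factor[i]))
    pop = pd.DataFrame(rows, columns=["region", "year", "population"])

    if constant_penetration:
        pi = [config.penetration_start] * len(years)
    else:
        pi = [config.penetration_start * (1.0 + config.penetration_growth) ** j
              for j in range(len(years))]
    pen = pd.DataFrame({"year": years, "penetration": pi})
    return pop, pen


def gen_covariates(config: ScenarioConfig):
    """Generate the covariate panel and the latent severity it induces.

    Covariates are iid standard normal per (region, year); per-capita GDP is
    a region-level lognormal base growing 5%/year. Severity is
    ``s = sum_k effect_k * x_k + N(0, noise_sd)``.
    Returns (covariate panel, severity table).
    """
    rng = config.rng(_STREAM_COV)
    regions, years = config.region_names, config.year_list
    n = len(regions) * len(years)
    panel = pd.DataFrame({
        "region": np.repeat(regions, len(years)),
        "year": np.tile(years, len(regions)),
    })
    for name in COVARIATE_NAMES:
        panel[name] = rng.normal(0.0, 1.0, n)
    gdp_base = np.exp(rng.normal(11.0, 0.4, len(regions)))
    growth = (1.05 ** (panel["year"] - years[0])).values
    panel["gdp_pc"] = np.repeat(gdp_base, len(years)) * growth

    s = np.zeros(n)
    for name, effect in config.effect_sizes.items():
        s += float(effect) * panel[name].values
    if config.noise_sd > 0:
        s += rng.normal(0.0, config.noise_sd, n)
    severity = panel[["region", "year"]].copy()
    severity["s"] = s
    return panel, severity


def gen_survey(config: ScenarioConfig, severity: pd.DataFrame,
               year: Optional[int] = None) -> pd.DataFrame:
    """Generate survey microdata (region, weight, disorder) for one year.

    Disorder probability is a logistic function of the region's standardised
    severity around the base prevalence; sampling weights are lognormal.
    """
    if severity is None or len(severity) == 0:
        raise ValueError("severity table is empty")
    rng = config.rng(_STREAM_SURVEY)
    year = int(year if year is not None else config.effective_survey_year)
    sub = severity[severity["year"] == year]
    if sub.empty:
        raise ValueError(f"severity has no rows for survey year {year}")
    s = sub["s"].values
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    p = expit(logit(config.survey_base_prevalence) + config.survey_slope * z)

    m = config.survey_n_per_region
    rows = []
    for (region, prob) in zip(sub["region"], p):
        weights = np.exp(rng.normal(0.0, 0.5, m))
        disorder = (rng.random(m) < prob).astype(int)
        rows.append(pd.DataFrame({"region": region, "weight": weights,
                                  "disorder": disorder}))
    return pd.concat(rows, ignore_index=True)


def gen_covariates_survey(config: ScenarioConfig):
    """Covariates, the severity they induce, and the survey drawn from it."""
    covariates, severity = gen_covariates(config)
    survey = gen_survey(config, severity)
    return covariates, severity, survey


def simulate_scenario(config: ScenarioConfig) -> dict:
    """Generate every input stream of the study under one config.

    Returns a dict with keys: corpus, trends, population, penetration,
    covariates, survey, severity, relevance (the last two are ground truth,
    not pipeline inputs).
    """
    covariates, severity, survey = gen_covariates_survey(config)
    population, penetration = gen_population_penetration(config)
    relevance = true_relevance(config)
    trends = gen_trend_panel(config, severity,
                             dict(zip(relevance["word"], relevance["relevance"])),
                             populations=population)
    corpus = gen_corpus(config)
    return {
        "corpus": corpus,
        "trends": trends,
        "population": population,
        "penetration": penetration,
        "covariates": covariates,
        "survey": survey,
        "severity": severity,
        "relevance": relevance,
    }
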