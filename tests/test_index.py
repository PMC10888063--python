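"""Index synthesis: yearly means, weights, efficacy scoring, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cadi.index import (CADIModel, aggregate_yearly, compute_cadi,
                        compute_weights, efficacy_score, penetration_adjust,
                        population_adjust, split_national, yearly_average)
from conftest import cadi_oracle, random_balanced_panel


def series(dates, values):
    return pd.DataFrame({"date": dates, "value": values})


class TestYearlyAverage:
    def test_constant_series(self):
        dates = pd.date_range("2020-01-01", "2020-12-30", freq="D")
        assert yearly_average(series(dates, 3.5), 2020) == pytest.approx(3.5)

    def test_small_mean(self):
        dates = ["2020-01-01", "2020-02-01", "2020-03-01", "2020-04-01"]
        assert yearly_average(series(dates, [1, 2, 3, 4]), 2020) == 2.5

    def test_missing_days_brute_force(self):
        rng = np.random.default_rng(2)
        dates = pd.date_range("2019-01-01", "2019-12-31", freq="D")
        keep = rng.random(len(dates)) > 0.1
        vals = rng.uniform(0, 50, len(dates))
        df = series(dates[keep], vals[keep])
        assert yearly_average(df, 2019) == pytest.approx(
            sum(vals[keep]) / keep.sum())

    def test_no_observations_raises(self):
        df = series(["2020-05-01"], [1.0])
        with pytest.raises(ValueError, match="2021"):
            yearly_average(df, 2021, label="w0")


class TestComputeWeights:
    def _pod(self, alphas):
        return pd.DataFrame({"word": [f"w{i}" for i in range(len(alphas))],
                             "alpha": alphas,
                             "frequency": 10})

    def _national(self, betas, year=2020):
        return pd.DataFrame({"word": [f"w{i}" for i in range(len(betas))],
                             "year": year, "beta": betas})

    def test_symmetric(self):
        w = compute_weights(self._pod([1.0, 1.0]), self._national([2.0, 2.0]))
        assert w["w"].tolist() == [0.5, 0.5]

    def test_direct_arithmetic(self):
        w = compute_weights(self._pod([1.0, 3.0]), self._national([1.0, 1.0]))
        assert w["w"].tolist() == pytest.approx([0.25, 0.75])

    def test_brute_force_normalization(self):
        rng = np.random.default_rng(4)
        alphas = rng.uniform(0, 1, 20)
        years = [2019, 2020]
        national = pd.concat([self._national(rng.uniform(0, 100, 20), y)
                              for y in years], ignore_index=True)
        w = compute_weights(self._pod(alphas), national)
        for y in years:
            betas = national[national["year"] == y].set_index("word")["beta"]
            phi = {f"w{i}": alphas[i] * betas[f"w{i}"] for i in range(20)}
            total = sum(phi.values())
            sub = w[w["year"] == y].set_index("word")
            for word in phi:
                assert sub.loc[word, "w"] == pytest.approx(phi[word] / total)
            assert sub["w"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_phi_year_raises(self):
        with pytest.raises(ValueError, match="zero"):
            compute_weights(self._pod([0.0, 0.0]), self._national([1.0, 2.0]))

    def test_missing_beta_raises(self):
        national = self._national([1.0])  # only w0
        with pytest.raises(ValueError, match="w1"):
            compute_weights(self._pod([0.5, 0.5]), national)


class TestPopulationAdjust:
    def _panel(self):
        return pd.DataFrame({"region": ["A"], "word": ["w0"], "year": [2020],
                             "gamma": [100.0]})

    def test_direct_division(self):
        pop = pd.DataFrame({"region": ["A"], "year": [2020],
                            "population": [1e7]})
        out = population_adjust(self._panel(), pop)
        assert out["gamma_bar"].iloc[0] == pytest.approx(1e-5)

    def test_equal_population_preserves_ranking(self):
        rng = np.random.default_rng(6)
        panel = pd.DataFrame({
            "region": list("ABCD") * 2, "word": ["w0"] * 4 + ["w1"] * 4,
            "year": 2020, "gamma": rng.uniform(0, 10, 8)})
        pop = pd.DataFrame({"region": list("ABCD"), "year": 2020,
                            "population": 5e6})
        out = population_adjust(panel, pop)
        for w in ("w0", "w1"):
            sub = out[out["word"] == w]
            assert (sub["gamma"].rank() == sub["gamma_bar"].rank()).all()

    def test_brute_force_elementwise(self):
        rng = np.random.default_rng(6)
        regions = [f"R{i}" for i in range(5)]
        panel = pd.DataFrame({
            "region": np.repeat(regions, 3),
            "word": ["w0", "w1", "w2"] * 5, "year": 2020,
            "gamma": rng.uniform(0, 100, 15)})
        pop = pd.DataFrame({"region": regions, "year": 2020,
                            "population": rng.uniform(1e6, 9e6, 5)})
        out = population_adjust(panel, pop)
        pmap = dict(zip(pop["region"], pop["population"]))
        for row in out.itertuples():
            assert row.gamma_bar == pytest.approx(row.gamma / pmap[row.region])

    def test_missing_population_named(self):
        pop = pd.DataFrame({"region": ["B"], "year": [2020],
                            "population": [1e6]})
        with pytest.raises(ValueError, match=r"\('A', 2020\)"):
            population_adjust(self._panel(), pop)

    def test_nonpositive_population_rejected(self):
        pop = pd.DataFrame({"region": ["A"], "year": [2020],
                            "population": [0.0]})
        with pytest.raises(ValueError, match="population"):
            population_adjust(self._panel(), pop)


class TestEfficacyScore:
    def test_anchors_60_and_100(self):
        assert efficacy_score(2.0, 2.0, 9.0, 40.0) == 60.0
        assert efficacy_score(9.0, 2.0, 9.0, 40.0) == 100.0

    def test_midpoint(self):
        assert efficacy_score(5.5, 2.0, 9.0, 40.0) == pytest.approx(80.0)

    def test_degenerate_indicator_scores_midrange(self):
        assert efficacy_score(3.0, 3.0, 3.0, 40.0) == pytest.approx(80.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            efficacy_score(1.0, 2.0, 9.0, 40.0)

    def test_invalid_tau_rejected(self):
        for tau in (0.0, -5.0, 100.5):
            with pytest.raises(ValueError, match="tau"):
                efficacy_score(2.0, 2.0, 9.0, tau)


class TestComputeCadi:
    def test_min_region_scores_60_max_scores_100(self):
        rng = np.random.default_rng(13)
        panel, weights = random_balanced_panel(rng, regions=5, words=10,
                                               years=(2020,))
        lo = panel.groupby("word")["gamma_bar"].transform("min")
        hi = panel.groupby("word")["gamma_bar"].transform("max")
        panel.loc[panel["region"] == "R00", "gamma_bar"] = \
            lo[panel["region"] == "R00"]
        panel.loc[panel["region"] == "R04", "gamma_bar"] = \
            hi[panel["region"] == "R04"]
        out = compute_cadi(panel, weights, tau=40.0).set_index("region")
        assert out.loc["R00", "cadi"] == pytest.approx(60.0, abs=1e-9)
        assert out.loc["R04", "cadi"] == pytest.approx(100.0, abs=1e-9)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(13)
        panel, weights = random_balanced_panel(rng)
        out = compute_cadi(panel, weights, tau=40.0)
        oracle = cadi_oracle(panel, weights, 40.0)
        for row in out.itertuples():
            assert row.cadi == pytest.approx(oracle[(row.region, row.year)],
                                             abs=1e-10)
            assert 60.0 - 1e-9 <= row.cadi <= 100.0 + 1e-9

    def test_unbalanced_panel_rejected(self):
        rng = np.random.default_rng(1)
        panel, weights = random_balanced_panel(rng, regions=3, words=4,
                                               years=(2020,))
        panel = panel.drop(panel.index[(panel["region"] == "R01")
                                       & (panel["word"] == "w02")])
        with pytest.raises(ValueError, match="unbalanced"):
            compute_cadi(panel, weights)

    def test_single_region_rejected(self):
        rng = np.random.default_rng(1)
        panel, weights = random_balanced_panel(rng, regions=1, words=3,
                                               years=(2020,))
        with pytest.raises(ValueError, match="2 regions"):
            compute_cadi(panel, weights)

    def test_monotone_in_own_trend(self):
        """Raising one region's adjusted trend inside a fixed min/max
        envelope never lowers its index."""
        rng = np.random.default_rng(17)
        panel, weights = random_balanced_panel(rng, regions=4, words=6,
                                               years=(2020,))
        # pin the envelope on two other regions
        panel.loc[panel["region"] == "R00", "gamma_bar"] = 0.0
        panel.loc[panel["region"] == "R01", "gamma_bar"] = 10.0
        previous = None
        for level in np.linspace(0.0, 10.0, 7):
            p = panel.copy()
            p.loc[p["region"] == "R02", "gamma_bar"] = level
            val = compute_cadi(p, weights).set_index("region").loc["R02",
                                                                   "cadi"]
            if previous is not None:
                assert val >= previous - 1e-12
            previous = val

    def test_affine_invariance_per_word(self):
        rng = np.random.default_rng(23)
        panel, weights = random_balanced_panel(rng)
        base = compute_cadi(panel, weights)
        transformed = panel.copy()
        for (word, year), idx in transformed.groupby(["word", "year"]).groups.items():
            a, b = rng.uniform(0.5, 3.0), rng.uniform(-5.0, 5.0)
            transformed.loc[idx, "gamma_bar"] = \
                a * transformed.loc[idx, "gamma_bar"] + b
        out = compute_cadi(transformed, weights)
        np.testing.assert_allclose(out["cadi"], base["cadi"], atol=1e-9)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_weight_normalization_property(data):
    """Weights always sum to one within each year."""
    n_words = data.draw(st.integers(1, 8))
    n_years = data.draw(st.integers(1, 3))
    alphas = data.draw(st.lists(
        st.floats(0.0, 1.0, allow_nan=False), min_size=n_words,
        max_size=n_words))
    pod = pd.DataFrame({"word": [f"w{i}" for i in range(n_words)],
                        "alpha": alphas, "frequency": 1})
    rows = []
    for y in range(2016, 2016 + n_years):
        betas = data.draw(st.lists(
            st.floats(0.0, 1e4, allow_nan=False), min_size=n_words,
            max_size=n_words))
        rows += [(f"w{i}", y, b) for i, b in enumerate(betas)]
    national = pd.DataFrame(rows, columns=["word", "year", "beta"])
    phi_by_year = national.merge(pod)["alpha"].mul(
        national["beta"]).groupby(national["year"]).sum()
    if (phi_by_year <= 0).any():
        with pytest.raises(ValueError):
            compute_weights(pod, national)
        return
    w = compute_weights(pod, national)
    sums = w.groupby("year")["w"].sum()
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert (w["w"] >= 0).all()


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 31 - 1),
       tau=st.floats(1.0, 100.0, allow_nan=False))
def test_cadi_bounds_property(seed, tau):
    """Every index value is a convex combination of per-word scores and
    therefore lies in [100 - tau, 100]."""
    rng = np.random.default_rng(seed)
    panel, weights = random_balanced_panel(rng, regions=4, words=5,
                                           years=(2020,))
    out = compute_cadi(panel, weights, tau=tau)
    assert (out["cadi"] >= 100.0 - tau - 1e-9).all()
    assert (out["cadi"] <= 100.0 + 1e-9).all()


class TestPenetrationAdjust:
    def _cadi(self):
        return pd.DataFrame({"region": ["A", "A", "A"],
                             "year": [2018, 2019, 2020],
                             "cadi": [80.0, 80.0, 80.0], "tau": 40.0})

    def test_constant_penetration_identity(self):
        pen = pd.DataFrame({"year": [2018, 2019, 2020], "penetration": 0.6})
        out = penetration_adjust(self._cadi(), pen)
        np.testing.assert_allclose(out["cadi_adjusted"], out["cadi"])

    def test_direct_ratio(self):
        pen = pd.DataFrame({"year": [2018, 2019, 2020],
                            "penetration": [0.5, 0.55, 0.55]})
        out = penetration_adjust(self._cadi(), pen).set_index("year")
        assert out.loc[2019, "cadi_adjusted"] == pytest.approx(88.0)
        assert out.loc[2018, "cadi_adjusted"] == pytest.approx(80.0)  # ratio 1

    def test_compounding_not_applied(self):
        pen = pd.DataFrame({"year": [2018, 2019, 2020],
                            "penetration": [0.5, 0.5 * 1.05, 0.5 * 1.05 ** 2]})
        out = penetration_adjust(self._cadi(), pen).set_index("year")
        # each year's ratio is 1.05 against the previous year, not cumulative
        assert out.loc[2020, "cadi_adjusted"] == pytest.approx(80.0 * 1.05)

    def test_missing_previous_year_rejected(self):
        pen = pd.DataFrame({"year": [2019, 2020], "penetration": [0.5, 0.55]})
        cadi = self._cadi()[self._cadi()["year"] >= 2019].copy()
        cadi.loc[:, "year"] = [2019, 2020]
        ok = penetration_adjust(cadi, pen)  # 2019 is the first year: ratio 1
        assert ok["cadi_adjusted"].iloc[0] == 80.0
        with pytest.raises(ValueError, match="2018"):
            penetration_adjust(self._cadi(), pen)


class TestCADIModel:
    def test_end_to_end_rank_recovery_noise_free(self, tiny_config):
        from cadi.synthetic import (gen_covariates, gen_population_penetration,
                                    gen_trend_panel, true_relevance)
        from dataclasses import replace
        from scipy import stats
        cfg = replace(tiny_config, noise_sd=0.0)
        _, severity = gen_covariates(cfg)
        pop, pen = gen_population_penetration(cfg)
        rel = true_relevance(cfg)
        trends = gen_trend_panel(cfg, severity,
                                 dict(zip(rel["word"], rel["relevance"])),
                                 populations=pop)
        pod = rel.rename(columns={"relevance": "alpha"}).assign(frequency=10)
        model = CADIModel(tau=40.0).fit(trends, pod, pop, pen)
        merged = model.cadi_.merge(severity, on=["region", "year"])
        for _, g in merged.groupby("year"):
            assert stats.spearmanr(g["cadi"], g["s"]).statistic == \
                pytest.approx(1.0)

    def test_national_rows_required(self, tiny_config):
        rng = np.random.default_rng(0)
        panel, _ = random_balanced_panel(rng, regions=3, words=2,
                                         years=(2020,))
        trends = panel.rename(columns={"gamma_bar": "value"})
        trends["date"] = "2020-06-01"
        pod = pd.DataFrame({"word": ["w00", "w01"], "alpha": 0.5,
                            "frequency": 5})
        pop = pd.DataFrame({"region": ["R00", "R01", "R02"], "year": 2020,
                            "population": 1e6})
        with pytest.raises(ValueError, match="NATIONAL"):
            CADIModel().fit(trends[["region", "word", "date", "value"]],
                            pod, pop)
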