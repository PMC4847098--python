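"""Summaries, DIC, component ratios, PSRF, MC error and exports."""

import numpy as np
import pandas as pd
import pytest

from bmda import (
    AreaTable,
    ModelSpec,
    PosteriorDraws,
    component_ratio,
    compute_dic,
    export_results,
    fit_result,
    gelman_rubin,
    intercept_only_dic,
    mc_error,
    summarize,
)
from bmda.posterior_summary import DEFAULT_PROBS
from helpers import chain_graph, small_table


def make_draws(model, scalars, fields=None, deviance=None, mlt=None, n_areas=4):
    spec = ModelSpec(model)
    scalars = {k: np.asarray(v, dtype=float) for k, v in scalars.items()}
    fields = {k: np.asarray(v, dtype=float) for k, v in (fields or {}).items()}
    any_arr = next(iter(scalars.values()))
    dev = np.asarray(deviance, float) if deviance is not None else np.zeros(any_arr.shape)
    return PosteriorDraws(
        model=spec, scalars=scalars, fields=fields, deviance=dev,
        mean_log_theta=mlt or {}, n_areas=n_areas,
    )


def single_area_table(y=2, e=1.0):
    return AreaTable(area_id=["a"], population=[100.0], y1=[y], e1=[e])


class TestSummarize:
    def test_point_mass_gives_zero_width(self):
        d = make_draws("cm-shr", {"alpha1": [[1.5] * 10]})
        s, _ = summarize(d)
        assert s.loc["alpha1", "q05"] == s.loc["alpha1", "q95"] == 1.5

    def test_median_of_1_to_100(self):
        d = make_draws("cm-shr", {"alpha1": [np.arange(1.0, 101.0)]})
        s, _ = summarize(d)
        assert s.loc["alpha1", "q50"] == pytest.approx(50.5)

    def test_quantiles_match_sort_oracle(self, rng):
        x = rng.normal(size=(2, 500))
        d = make_draws("cm-shr", {"alpha1": x})
        s, _ = summarize(d)
        pool = np.sort(x.reshape(-1))
        for p, col in zip(DEFAULT_PROBS, ["q05", "q50", "q95"]):
            assert s.loc["alpha1", col] == pytest.approx(np.quantile(pool, p))

    def test_variance_rows_are_reciprocal_precisions(self, rng):
        tau = rng.uniform(1, 5, size=(1, 200))
        d = make_draws("cm-shr", {"tau_v1": tau})
        s, _ = summarize(d)
        assert s.loc["sigma2_v1", "q50"] == pytest.approx(np.median(1 / tau))

    def test_empty_draws_rejected(self):
        d = make_draws("cm-shr", {"alpha1": np.empty((1, 0))})
        with pytest.raises(ValueError, match="empty"):
            summarize(d)


class TestDic:
    def test_point_mass_posterior_has_zero_pd(self):
        table = single_area_table(y=2, e=1.0)
        dev = -2 * (np.log(2) - 2)  # deviance with log theta = log 2
        d = make_draws("cm-shr", {"alpha1": [[np.log(2)] * 5]},
                       deviance=[[dev] * 5], mlt={1: np.array([np.log(2)])},
                       n_areas=1)
        res = compute_dic(d, d.model, table)
        assert res.pd == pytest.approx(0.0, abs=1e-12)
        assert res.dic == pytest.approx(-2 * (np.log(2) - 2), abs=1e-12)

    def test_dic_identity(self, rng):
        """DIC = 2*Dbar - D(theta_bar) by construction."""
        table = single_area_table()
        dev = 2.6 + rng.uniform(0, 1, size=(2, 50))
        d = make_draws("cm-shr", {"alpha1": np.zeros((2, 50))}, deviance=dev,
                       mlt={1: np.array([np.log(2)])}, n_areas=1)
        res = compute_dic(d, d.model, table)
        assert res.dic == pytest.approx(2 * res.dbar - res.d_at_mean, abs=1e-12)
        assert res.pd == pytest.approx(res.dbar - res.d_at_mean, abs=1e-12)

    def test_intercept_only_baseline_pd_near_one(self, rng):
        t = small_table(20, rng, mean_count=100)
        res = intercept_only_dic(t, (1,), rng, n_draws=20000)
        assert 0.7 < res.pd < 1.3  # one free parameter


class TestComponentRatio:
    def _m1_draws(self, beta, u1, v1):
        return make_draws("cm-shr", {"alpha1": [np.zeros(len(beta))],
                                     "beta": [beta]},
                          fields={"u1": [u1], "v1": [v1]})

    def test_zero_residual_fields_give_ratio_one(self, rng):
        t = small_table(4, rng)
        T = 3
        d = self._m1_draws(np.ones(T), np.zeros((T, 4)), np.zeros((T, 4)))
        r = component_ratio(d, d.model, t)
        assert (r.median, r.q05, r.q95) == (1.0, 1.0, 1.0)

    def test_constant_component_gives_ratio_zero(self, rng):
        t = small_table(4, rng)
        t.shr2 = np.full(4, 1.3)  # constant covariate -> constant component
        d = self._m1_draws(np.ones(3), np.random.default_rng(0).normal(size=(3, 4)),
                           np.zeros((3, 4)))
        r = component_ratio(d, d.model, t)
        assert (r.median, r.q05, r.q95) == (0.0, 0.0, 0.0)

    def test_hand_computed_three_draw_example(self, rng):
        t = small_table(4, rng)
        beta = np.array([0.5, 1.0, -2.0])
        u1 = np.arange(12.0).reshape(3, 4)
        v1 = np.array([[0.1, -0.2, 0.3, 0.0]] * 3)
        d = self._m1_draws(beta, u1, v1)
        got = component_ratio(d, d.model, t)
        ratios = []
        for k in range(3):  # independent spreadsheet-style computation
            c = beta[k] * t.shr2
            tot = c + u1[k] + v1[k]
            ratios.append(np.var(c, ddof=1) / np.var(tot, ddof=1))
        assert got.median == pytest.approx(np.median(ratios), abs=1e-12)
        assert got.q05 == pytest.approx(np.quantile(ratios, 0.05), abs=1e-12)
        assert got.q95 == pytest.approx(np.quantile(ratios, 0.95), abs=1e-12)

    def test_invariant_to_constant_component_shift(self, rng):
        """Adding a constant to the component leaves every draw's ratio unchanged."""
        t = small_table(4, rng)
        beta = np.array([1.0, 2.0])
        u1 = rng.normal(size=(2, 4))
        v1 = rng.normal(size=(2, 4))
        base = component_ratio(self._m1_draws(beta, u1, v1), ModelSpec("cm-shr"), t)
        t2 = t.copy()
        t2.shr2 = t.shr2 + 5.0  # shifts the component by beta*5 per draw
        shifted = component_ratio(self._m1_draws(beta, u1 - 5.0 * beta[:, None] * 0,
                                                 v1), ModelSpec("cm-shr"), t2)
        assert shifted.median == pytest.approx(base.median, rel=1e-9)

    def test_zero_total_variance_draws_excluded(self, rng):
        t = small_table(4, rng)
        t.shr2 = np.full(4, 1.0)
        beta = np.array([1.0, 1.0])
        u1 = np.array([np.zeros(4), [0.0, 1.0, 2.0, 3.0]])
        d = self._m1_draws(beta, u1, np.zeros((2, 4)))
        r = component_ratio(d, d.model, t)
        assert r.n_missing == 1
        assert r.median == 0.0


def psrf_oracle(x):
    """Independent PSRF from the classic between/within decomposition."""
    k, m = x.shape
    means = x.mean(axis=1)
    w = np.mean([np.var(x[c], ddof=1) for c in range(k)])
    b = m / (k - 1) * np.sum((means - means.mean()) ** 2)
    return np.sqrt(((m - 1) / m * w + b / m) / w)


class TestGelmanRubin:
    def test_identical_chains(self):
        x = np.vstack([np.arange(20.0)] * 2)
        assert gelman_rubin(x) == pytest.approx(np.sqrt(19 / 20))
        assert gelman_rubin(x) < 1

    def test_separated_chains(self, rng):
        x = np.vstack([rng.normal(0, 1, 100), rng.normal(100, 1, 100)])
        assert gelman_rubin(x) > 1.2

    def test_matches_independent_oracle(self, rng):
        x = rng.normal(size=(4, 250))
        assert gelman_rubin(x) == pytest.approx(psrf_oracle(x), abs=1e-8)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestMcError:
    def test_iid_draws_close_to_sd_over_sqrt_m(self, rng):
        x = rng.normal(size=(1, 10000))
        res = mc_error(x)
        expected = x.std(ddof=1) / np.sqrt(10000)
        assert res.se == pytest.approx(expected, rel=0.5)
        assert res.ok

    def test_constant_draws_zero_error(self):
        res = mc_error(np.ones((1, 100)))
        assert res.se == 0.0 and res.ratio == 0.0

    def test_slowly_mixing_sequence_flagged(self):
        x = np.sin(np.linspace(0, 2, 400))[None, :]  # near-monotone drift
        res = mc_error(x)
        assert res.ratio >= 0.05 and not res.ok

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            mc_error(np.zeros((1, 10)))


@pytest.fixture(scope="module")
def small_fit():
    from bmda import SamplerConfig, run_chains
    from bmda.synthetic_data import ScenarioConfig, simulate_dataset

    table, graph, _ = simulate_dataset(ScenarioConfig(rows=3, cols=3, seed=4),
                                       "cm-shr")
    spec = ModelSpec("cm-shr")
    cfg = SamplerConfig(n_chains=2, n_burnin=100, n_iter=300, seed=2)
    draws = run_chains(spec, table, graph, cfg)
    return table, graph, spec, fit_result(draws, spec, table, graph)


class TestExport:
    def test_round_trip_and_order(self, small_fit, tmp_path):
        table, graph, spec, fit = small_fit
        paths = export_results(fit, table, tmp_path)
        df = pd.read_csv(paths["area_csv"])
        assert list(df["area_id"]) == list(table.area_id)
        np.testing.assert_allclose(df["rr1_q50"], fit.area_summary["rr1_q50"])
        assert paths["summary_json"].exists()

    def test_class_bins(self, small_fit, tmp_path):
        from bmda.posterior_summary import _class_bin

        assert _class_bin(np.array([1.6]), (0.5, 1.0, 1.5)) == [">1.5"]
        assert _class_bin(np.array([0.2]), (0.5, 1.0, 1.5)) == ["<0.5"]
        assert _class_bin(np.array([1.2]), (0.5, 1.0, 1.5)) == ["1-1.5"]

    def test_dic_identity_on_real_fit(self, small_fit):
        _, _, _, fit = small_fit
        assert fit.dic.pd == pytest.approx(fit.dic.dbar - fit.dic.d_at_mean)
        assert fit.dic.dic == pytest.approx(fit.dic.dbar + fit.dic.pd)
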