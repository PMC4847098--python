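"""Sampler correctness: local ratios, block updates, conjugacy, recovery."""

import numpy as np
import pytest
from scipy.stats import kstest

from bmda import (
    ModelSpec,
    SamplerConfig,
    joint_log_posterior,
    local_log_ratio,
    run_chain,
    run_chains,
    update_precisions,
    update_site,
)
from bmda.sampler import _ChainRunner
from bmda.synthetic_data import ScenarioConfig, make_grid_graph, simulate_dataset
from helpers import all_sites, chain_graph, random_state, small_table

MODELS = ["cm-shr", "cm-struct", "scm"]


def set_site(state, site, value):
    name, idx = site
    out = state.copy()
    if idx is None:
        setattr(out, name, value)
    else:
        getattr(out, name)[idx] = value
    return out


class TestLocalRatio:
    @pytest.mark.parametrize("model", MODELS)
    def test_local_equals_full_joint_difference(self, rng, model):
        table = small_table(4, rng)
        graph = chain_graph(4)
        spec = ModelSpec(model)
        sites = all_sites(spec, graph)
        for _ in range(60):
            st = random_state(spec, table, graph, rng)
            site = sites[rng.integers(len(sites))]
            cur = getattr(st, site[0]) if site[1] is None else getattr(st, site[0])[site[1]]
            new = float(cur + rng.normal(0, 0.5))
            local = local_log_ratio(spec, st, table, graph, site, new)
            full = joint_log_posterior(spec, set_site(st, site, new), table, graph) \
                - joint_log_posterior(spec, st, table, graph)
            assert local == pytest.approx(full, abs=1e-9)

    @pytest.mark.parametrize("model", MODELS)
    def test_identity_proposal_has_zero_ratio(self, rng, model):
        table = small_table(4, rng)
        graph = chain_graph(4)
        spec = ModelSpec(model)
        st = random_state(spec, table, graph, rng)
        for site in all_sites(spec, graph):
            cur = getattr(st, site[0]) if site[1] is None else getattr(st, site[0])[site[1]]
            assert local_log_ratio(spec, st, table, graph, site, float(cur)) == \
                pytest.approx(0.0, abs=1e-12)

    def test_update_site_zero_step_always_accepts(self, rng):
        table = small_table(4, rng)
        graph = chain_graph(4)
        spec = ModelSpec("scm")
        st = random_state(spec, table, graph, rng)
        for site in [("alpha1", None), ("log_delta", None), ("u1", 1), ("v2", 3)]:
            _, accepted = update_site(st, site, spec, table, graph, rng, step=0.0)
            assert accepted


class TestBlockUpdatesMatchPerSite:
    """The vectorized colour-block sweep must make exactly the per-site decisions."""

    @pytest.mark.parametrize(
        "model, field",
        [("cm-shr", "u1"), ("cm-struct", "u2"), ("scm", "phi"), ("scm", "v1"),
         ("cm-struct", "v2")],
    )
    def test_field_block(self, rng, model, field):
        table = small_table(9, rng)
        graph = make_grid_graph(3, 3)
        spec = ModelSpec(model)
        init = random_state(spec, table, graph, rng)
        cfg = SamplerConfig(n_chains=1, n_burnin=0, n_iter=1, seed=0)
        runner = _ChainRunner(spec, table, graph, cfg, np.random.default_rng(42), init)
        replay = np.random.default_rng(42)

        oracle_state = runner.state.copy()
        f_oracle = getattr(oracle_state, field)
        if field in ("u1", "u2", "phi"):
            blocks = runner.colors
        else:
            blocks = [np.arange(graph.n)]
        for C in blocks:
            z = replay.standard_normal(len(C))
            logu = np.log(replay.uniform(size=len(C)))
            for k, i in enumerate(C):
                prop = float(f_oracle[i] + runner.steps_field[field][i] * z[k])
                ratio = local_log_ratio(spec, oracle_state, table, graph,
                                        (field, int(i)), prop)
                if logu[k] < ratio:
                    f_oracle[i] = prop

        if field in ("u1", "u2", "phi"):
            runner._update_icar_field(field)
        else:
            runner._update_v_field(field)
        np.testing.assert_allclose(getattr(runner.state, field), f_oracle,
                                   atol=1e-12)

    @pytest.mark.parametrize("model", MODELS)
    def test_scalar_updates(self, rng, model):
        table = small_table(9, rng)
        graph = make_grid_graph(3, 3)
        spec = ModelSpec(model)
        init = random_state(spec, table, graph, rng)
        cfg = SamplerConfig(n_chains=1, n_burnin=0, n_iter=1, seed=0)
        runner = _ChainRunner(spec, table, graph, cfg, np.random.default_rng(9), init)
        replay = np.random.default_rng(9)

        oracle_state = runner.state.copy()
        for name in spec.scalar_params():
            z = float(replay.standard_normal())
            logu = float(np.log(replay.uniform()))
            prop = float(getattr(oracle_state, name) + runner.steps_scalar[name] * z)
            ratio = local_log_ratio(spec, oracle_state, table, graph, (name, None), prop)
            if logu < ratio:
                setattr(oracle_state, name, prop)
            if name == "alpha1":
                runner._update_intercept("alpha1", 1)
            elif name == "alpha2":
                runner._update_intercept("alpha2", 2)
            elif name == "beta":
                runner._update_beta()
            else:
                runner._update_log_delta()
            assert getattr(runner.state, name) == pytest.approx(
                getattr(oracle_state, name), abs=1e-12
            )


class TestPrecisionUpdates:
    def test_zero_v_field_samples_prior_rate(self, rng):
        """With v = 0 the conditional is Gamma(a + n/2, b) exactly (KS check)."""
        table = small_table(4, rng)
        graph = chain_graph(4)
        spec = ModelSpec("cm-shr")
        st = random_state(spec, table, graph, rng)
        st.v1 = np.zeros(4)
        a, b = spec.hyper.tau_gamma_a, spec.hyper.tau_gamma_b
        draws = np.array([
            update_precisions(st, spec, table, graph, rng).tau_v1
            for _ in range(2000)
        ])
        # scipy gamma with shape a+n/2; rescale by the rate b
        p = kstest(draws * b, "gamma", args=(a + 2.0,)).pvalue
        assert p > 1e-3

    def test_constant_icar_field_uses_rank_deficiency(self, rng):
        table = small_table(5, rng)
        graph = chain_graph(5)
        spec = ModelSpec("cm-shr")
        st = random_state(spec, table, graph, rng)
        st.u1 = np.full(5, 3.0)  # pairwise SS = 0
        a, b = spec.hyper.tau_gamma_a, spec.hyper.tau_gamma_b
        draws = np.array([
            update_precisions(st, spec, table, graph, rng).tau_u1
            for _ in range(2000)
        ])
        p = kstest(draws * b, "gamma", args=(a + (5 - 1) / 2,)).pvalue
        assert p > 1e-3


class TestChains:
    def test_same_seed_bitwise_identical(self, rng):
        table = small_table(9, rng)
        graph = make_grid_graph(3, 3)
        spec = ModelSpec("cm-struct")
        cfg = SamplerConfig(n_chains=1, n_burnin=50, n_iter=50, seed=11)
        d1 = run_chain(spec, table, graph, cfg)
        d2 = run_chain(spec, table, graph, cfg)
        for k in d1["scalars"]:
            np.testing.assert_array_equal(d1["scalars"][k], d2["scalars"][k])
        np.testing.assert_array_equal(d1["deviance"], d2["deviance"])

    def test_zero_iterations_gives_empty_draws(self, rng):
        table = small_table(4, rng)
        graph = chain_graph(4)
        cfg = SamplerConfig(n_chains=1, n_burnin=0, n_iter=0, seed=0)
        d = run_chain(ModelSpec("cm-shr"), table, graph, cfg)
        assert d["deviance"].size == 0
        assert all(v.size == 0 for v in d["scalars"].values())

    def test_chains_differ_and_pool_counts(self, rng):
        table = small_table(9, rng)
        graph = make_grid_graph(3, 3)
        cfg = SamplerConfig(n_chains=3, n_burnin=20, n_iter=40, thin=2, seed=5)
        draws = run_chains(ModelSpec("cm-shr"), table, graph, cfg)
        assert draws.n_chains == 3
        assert draws.n_draws == 20  # floor(40/2)
        assert draws.pooled("alpha1").size == 60
        a = draws.get("alpha1")
        assert not np.array_equal(a[0], a[1])

    def test_thin_invariants(self, rng):
        table = small_table(4, rng)
        graph = chain_graph(4)
        cfg = SamplerConfig(n_chains=1, n_burnin=10, n_iter=25, thin=4, seed=0)
        d = run_chain(ModelSpec("cm-shr"), table, graph, cfg)
        assert d["deviance"].shape == (6,)  # floor(25/4)


@pytest.fixture(scope="module")
def m1_fit_16():
    """Model-1 fit on a 16-area grid with simulated data (easy target)."""
    scenario = ScenarioConfig(rows=4, cols=4, seed=21)
    table, graph, truth = simulate_dataset(scenario, "cm-shr")
    cfg = SamplerConfig(n_chains=3, n_burnin=1000, n_iter=5000, seed=77,
                        store_fields=False)
    draws = run_chains(ModelSpec("cm-shr"), table, graph, cfg)
    return draws, truth


class TestRecoverySmoke:
    def test_beta_recovered_within_3_sd(self, m1_fit_16):
        draws, truth = m1_fit_16
        b = draws.pooled("beta")
        assert abs(b.mean() - truth["beta"]) < 3 * b.std(ddof=1)

    def test_gelman_rubin_converged_on_easy_target(self, m1_fit_16):
        from bmda import gelman_rubin

        draws, _ = m1_fit_16
        for p in ["alpha1", "beta", "tau_u1", "tau_v1"]:
            assert gelman_rubin(draws.get(p)) < 1.05
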