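"""Metropolis-within-Gibbs MCMC engine for the areal models.

Precisions get exact conjugate Gamma updates; every other parameter gets an
adaptive Gaussian random-walk Metropolis update on its own coordinate.  The
acceptance ratio for a single coordinate only involves the likelihood and
prior factors that touch it; :func:`local_log_ratio` is that local
computation, and tests assert it equals the difference of the full joint
posterior.

For speed the chain loop updates spatial-field coordinates in colour blocks:
a greedy graph colouring partitions the areas so that no two areas in a block
are neighbours, hence their ICAR full conditionals do not interact and the
block of single-coordinate Metropolis moves can be executed with vectorized
numpy, with results identical to a per-coordinate loop.  Unstructured
(v-field) coordinates are conditionally independent given the rest and are
updated in one block.

Step sizes adapt toward a 0.44 acceptance rate during burn-in only
(Robbins-Monro rescaling), so the retained kernel is a fixed, valid Markov
chain.  After every sweep each ICAR field is recentred to per-component mean
zero with the subtracted global mean absorbed into the intercept(s) —
ICAR plus a flat intercept is unidentified otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .areal_data import AdjacencyGraph, AreaTable
from .icar_prior import IcarField, recenter, tau_posterior_params
from .model_specs import (
    ModelId,
    ModelSpec,
    ParamState,
    linear_predictor,
)

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "Site",
    "local_log_ratio",
    "update_site",
    "update_precisions",
    "initial_state",
    "run_chain",
    "run_chains",
]

Site = tuple[str, int | None]

_STEP_MIN, _STEP_MAX = 1e-5, 50.0


@dataclass
class SamplerConfig:
    """Chain lengths, seeding and adaptation settings."""

    n_chains: int = 3
    n_burnin: int = 2000
    n_iter: int = 5000
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44
    store_fields: bool = True
    # diagnostics / prior-checking modes
    prior_only: bool = False       # drop the likelihood; spatial fields pinned at 0
    fix_precisions: bool = False   # freeze all tau's at their initial values

    def __post_init__(self) -> None:
        if self.n_iter < 0 or self.n_burnin < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0,1)")


@dataclass
class PosteriorDraws:
    """Retained draws from all chains.

    ``scalars[name]`` has shape (n_chains, n_draws); ``fields[name]`` has
    shape (n_chains, n_draws, n_areas) and is empty when the sampler ran with
    ``store_fields=False``.  ``deviance`` is stored for every retained draw,
    and ``mean_log_theta[d]`` is the running posterior mean of the linear
    predictor per area (used for the DIC plug-in).
    """

    model: ModelSpec
    scalars: dict[str, np.ndarray]
    fields: dict[str, np.ndarray]
    deviance: np.ndarray
    mean_log_theta: dict[int, np.ndarray]
    n_areas: int
    config: SamplerConfig | None = None

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[1]

    def parameter_names(self) -> list[str]:
        return list(self.scalars)

    def get(self, name: str) -> np.ndarray:
        """Per-chain draws (n_chains, n_draws) of a scalar parameter."""
        if name not in self.scalars:
            raise KeyError(f"no scalar parameter {name!r}; have {list(self.scalars)}")
        return self.scalars[name]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def field(self, name: str) -> np.ndarray:
        if name not in self.fields:
            raise KeyError(
                f"field draws for {name!r} were not stored "
                "(sampler ran with store_fields=False)"
            )
        return self.fields[name]

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {"deviance": self.deviance}
        for k, v in self.scalars.items():
            arrays[f"scalar__{k}"] = v
        for k, v in self.fields.items():
            arrays[f"field__{k}"] = v
        for d, v in self.mean_log_theta.items():
            arrays[f"mlt__{d}"] = v
        np.savez_compressed(
            path,
            model=np.array(self.model.to_config()["model"]),
            hyper=np.array(list(self.model.to_config()["hyper"].items()), dtype=object),
            n_areas=np.array(self.n_areas),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=True) as z:
            hyper = {k: float(v) for k, v in z["hyper"]}
            spec = ModelSpec.from_config({"model": str(z["model"]), "hyper": hyper})
            scalars = {k[8:]: z[k] for k in z.files if k.startswith("scalar__")}
            fields_ = {k[7:]: z[k] for k in z.files if k.startswith("field__")}
            mlt = {int(k[5:]): z[k] for k in z.files if k.startswith("mlt__")}
            return cls(
                model=spec,
                scalars=scalars,
                fields=fields_,
                deviance=z["deviance"],
                mean_log_theta=mlt,
                n_areas=int(z["n_areas"]),
            )


# ---------------------------------------------------------------------------
# local Metropolis ratios (reference path; the chain loop vectorizes these)
# ---------------------------------------------------------------------------


def _poisson_delta(y, e, log_theta, dlt) -> float:
    """Change in Poisson log likelihood when log theta shifts by dlt."""
    mu = e * np.exp(log_theta)
    return float(np.sum(y * dlt - mu * np.expm1(dlt)))


def local_log_ratio(
    spec: ModelSpec,
    state: ParamState,
    table: AreaTable,
    graph: AdjacencyGraph,
    site: Site,
    new_value: float,
) -> float:
    """Log acceptance ratio for setting one scalar coordinate to ``new_value``.

    Only the factors of the joint posterior that involve the coordinate are
    evaluated; the result equals joint_log_posterior(new) - joint_log_posterior(old).
    """
    name, idx = site
    hp = spec.hyper
    prior_only = False
    cur_lik = {} if prior_only else {
        d: linear_predictor(spec, state, table, d) for d in spec.diseases
    }

    def lik_delta(disease: int, dlt: np.ndarray | float, where=None) -> float:
        lt = cur_lik[disease]
        y, e = np.asarray(table.y(disease), float), table.e(disease)
        if where is None:
            return _poisson_delta(y, e, lt, dlt)
        return _poisson_delta(y[where], e[where], lt[where], dlt)

    if name == "alpha1":
        d_ = new_value - state.alpha1
        return lik_delta(1, d_)
    if name == "alpha2":
        d_ = new_value - state.alpha2
        return lik_delta(2, d_)
    if name == "beta":
        d_ = new_value - state.beta
        x = table.shr(2) if spec.model_id is ModelId.CM_SHR else state.u2
        dprior = -0.5 * (new_value**2 - state.beta**2) / hp.beta_prior_var
        return lik_delta(1, d_ * x) + dprior
    if name == "log_delta":
        b1, b2 = state.beta1, state.beta2
        b1n, b2n = np.exp(new_value), np.exp(-new_value)
        dprior = -0.5 * (new_value**2 - state.log_delta**2) / hp.kappa_delta
        return (
            lik_delta(1, (b1n - b1) * state.phi)
            + lik_delta(2, (b2n - b2) * state.phi)
            + dprior
        )

    # field coordinates
    assert idx is not None, f"site {name} requires a coordinate index"
    f = getattr(state, name)
    old = f[idx]
    d_ = new_value - old
    out = 0.0
    if name in ("u1", "u2", "phi"):
        tau = getattr(state, f"tau_{name}")
        nb = graph.neighbours[idx]
        if len(nb) == 0:
            raise ValueError(f"isolated node {idx}: ICAR coordinate is pinned at 0")
        out += -0.5 * tau * float(
            np.sum((new_value - f[nb]) ** 2) - np.sum((old - f[nb]) ** 2)
        )
        if name == "u1":
            out += lik_delta(1, d_, where=[idx])
        elif name == "u2":
            if spec.model_id is ModelId.CM_STRUCT:
                out += lik_delta(1, state.beta * d_, where=[idx])
            out += lik_delta(2, d_, where=[idx])
        else:  # phi
            out += lik_delta(1, state.beta1 * d_, where=[idx])
            out += lik_delta(2, state.beta2 * d_, where=[idx])
    elif name in ("v1", "v2"):
        tau = getattr(state, f"tau_{name}")
        out += -0.5 * tau * (new_value**2 - old**2)
        out += lik_delta(1 if name == "v1" else 2, d_, where=[idx])
    else:
        raise ValueError(f"unknown site {name!r}")
    return float(out)


def update_site(
    state: ParamState,
    site: Site,
    spec: ModelSpec,
    table: AreaTable,
    graph: AdjacencyGraph,
    rng: np.random.Generator,
    step: float,
) -> tuple[ParamState, bool]:
    """One Gaussian random-walk Metropolis update of one scalar coordinate."""
    name, idx = site
    cur = getattr(state, name) if idx is None else getattr(state, name)[idx]
    if not np.isfinite(cur):
        raise RuntimeError(f"non-finite current value at site {site}")
    prop = float(cur + step * rng.standard_normal())
    ratio = local_log_ratio(spec, state, table, graph, site, prop)
    accept = np.log(rng.uniform()) < ratio
    if accept:
        out = state.copy()
        if idx is None:
            setattr(out, name, prop)
        else:
            getattr(out, name)[idx] = prop
        return out, True
    return state, False


def update_precisions(
    state: ParamState,
    spec: ModelSpec,
    table: AreaTable,
    graph: AdjacencyGraph,
    rng: np.random.Generator,
) -> ParamState:
    """Exact conjugate Gamma draws for every active precision."""
    hp = spec.hyper
    out = state.copy()
    for name in spec.icar_fields():
        fld = IcarField(getattr(state, name), graph, getattr(state, f"tau_{name}"))
        shape, rate = tau_posterior_params(fld, hp.tau_gamma_a, hp.tau_gamma_b)
        setattr(out, f"tau_{name}", float(rng.gamma(shape, 1.0 / rate)))
    for name in spec.v_fields():
        v = getattr(state, name)
        shape = hp.tau_gamma_a + 0.5 * graph.n
        rate = hp.tau_gamma_b + 0.5 * float(v @ v)
        setattr(out, f"tau_{name}", float(rng.gamma(shape, 1.0 / rate)))
    return out


# ---------------------------------------------------------------------------
# chain orchestration
# ---------------------------------------------------------------------------


def _color_classes(graph: AdjacencyGraph) -> list[np.ndarray]:
    """Greedy proper colouring; isolated nodes are excluded (pinned at 0)."""
    color = np.full(graph.n, -1, dtype=np.int64)
    for i in range(graph.n):
        if len(graph.neighbours[i]) == 0:
            continue
        used = {color[j] for j in graph.neighbours[i] if color[j] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.flatnonzero(color == c) for c in range(color.max(initial=-1) + 1)]


def initial_state(
    spec: ModelSpec,
    table: AreaTable,
    graph: AdjacencyGraph,
    rng: np.random.Generator,
    overdispersed: bool = True,
) -> ParamState:
    """Data-informed starting point with optional per-chain overdispersion.

    Intercepts start at the log of the pooled SHR mean, coefficients at 0,
    fields at small recentred jitter, precisions at 10; overdispersion adds
    Normal(0, 0.5) jitter to the scalar parameters.
    """
    n = table.n
    st = ParamState()
    jit = (lambda: float(rng.normal(0.0, 0.5))) if overdispersed else (lambda: 0.0)

    def small_field() -> np.ndarray:
        f = rng.normal(0.0, 0.1, size=n)
        return recenter(f, graph)[0]

    st.alpha1 = float(np.log(max(table.shr(1).mean(), 1e-8))) + jit()
    if spec.model_id is not ModelId.CM_SHR:
        st.alpha2 = float(np.log(max(table.shr(2).mean(), 1e-8))) + jit()
    if spec.model_id in (ModelId.CM_SHR, ModelId.CM_STRUCT):
        st.beta = jit()
    else:
        st.log_delta = jit()
    for name in spec.icar_fields():
        setattr(st, name, small_field())
        setattr(st, f"tau_{name}", 10.0)
    for name in spec.v_fields():
        setattr(st, name, rng.normal(0.0, 0.1, size=n))
        setattr(st, f"tau_{name}", 10.0)
    return st


class _ChainRunner:
    """Vectorized single-chain sweep engine (see module docstring)."""

    def __init__(
        self,
        spec: ModelSpec,
        table: AreaTable,
        graph: AdjacencyGraph,
        config: SamplerConfig,
        rng: np.random.Generator,
        init: ParamState,
    ) -> None:
        self.spec, self.table, self.graph = spec, table, graph
        self.cfg = config
        self.rng = rng
        self.n = graph.n
        self.hp = spec.hyper
        self.colors = _color_classes(graph)
        W = graph.adjacency_matrix()
        self.W_rows = [W[c, :] for c in self.colors]
        self.deg = graph.degrees.astype(float)
        self.isolated = graph.degrees == 0
        self.diseases = () if config.prior_only else spec.diseases
        self.y = {d: np.asarray(table.y(d), float) for d in self.diseases}
        self.e = {d: np.asarray(table.e(d), float) for d in self.diseases}
        self.loge = {d: np.log(self.e[d]) for d in self.diseases}
        self.dev_const = {
            d: float(np.sum(self.y[d] * self.loge[d] - gammaln(self.y[d] + 1.0)))
            for d in self.diseases
        }
        self.x_cov = table.shr(2) if spec.model_id is ModelId.CM_SHR else None
        # per-colour slices of the count data, for the hot field-update loop
        self.yC = {d: [self.y[d][c] for c in self.colors] for d in self.diseases}
        self.eC = {d: [self.e[d][c] for c in self.colors] for d in self.diseases}

        self.state = init.copy()
        if config.prior_only:
            for name in spec.icar_fields():
                setattr(self.state, name, np.zeros(self.n))
        for name in spec.icar_fields():  # pin isolated nodes
            getattr(self.state, name)[self.isolated] = 0.0
        self.logtheta: dict[int, np.ndarray] = {}
        self._refresh_logtheta()

        self.steps_scalar = {name: 0.1 for name in spec.scalar_params()}
        if spec.model_id is ModelId.CM_SHR:
            self.steps_scalar["beta_ridge"] = 0.1
        self.steps_field = {name: np.full(self.n, 0.1) for name in spec.field_params()}
        self._reset_counters()
        self.adapt_round = 0

    # -- bookkeeping --------------------------------------------------------

    def _refresh_logtheta(self) -> None:
        for d in self.diseases:
            self.logtheta[d] = linear_predictor(self.spec, self.state, self.table, d)

    def _reset_counters(self) -> None:
        self.acc_scalar = {k: 0 for k in self.steps_scalar}
        self.try_scalar = {k: 0 for k in self.steps_scalar}
        self.acc_field = {k: np.zeros(self.n) for k in self.steps_field}
        self.try_field = {k: np.zeros(self.n) for k in self.steps_field}

    def _adapt(self) -> None:
        self.adapt_round += 1
        gain = 1.0 / np.sqrt(self.adapt_round)
        tgt = self.cfg.target_accept
        for k, s in self.steps_scalar.items():
            if self.try_scalar[k]:
                rate = self.acc_scalar[k] / self.try_scalar[k]
                self.steps_scalar[k] = float(
                    np.clip(s * np.exp(gain * (rate - tgt)), _STEP_MIN, _STEP_MAX)
                )
        for k, s in self.steps_field.items():
            tried = self.try_field[k] > 0
            if tried.any():
                rate = np.where(tried, self.acc_field[k] / np.maximum(self.try_field[k], 1), tgt)
                self.steps_field[k] = np.clip(
                    s * np.exp(gain * (rate - tgt)), _STEP_MIN, _STEP_MAX
                )
        self._reset_counters()

    def deviance(self) -> float:
        dev = 0.0
        for d in self.diseases:
            lt = self.logtheta[d]
            dev += self.dev_const[d] + float(
                self.y[d] @ lt - np.sum(self.e[d] * np.exp(lt))
            )
        return -2.0 * dev

    # -- update steps --------------------------------------------------------

    def _lik_delta_vec(self, d: int, dlt: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Per-coordinate Poisson log-lik change at areas idx, shift dlt."""
        mu = self.e[d][idx] * np.exp(self.logtheta[d][idx])
        return self.y[d][idx] * dlt - mu * np.expm1(dlt)

    def _scalar_mh(self, name: str, log_ratio_fn, apply_fn) -> None:
        step = self.steps_scalar[name]
        z = float(self.rng.standard_normal())
        logu = float(np.log(self.rng.uniform()))
        d_ = step * z
        ratio, payload = log_ratio_fn(d_)
        self.try_scalar[name] += 1
        if logu < ratio:
            self.acc_scalar[name] += 1
            apply_fn(d_, payload)

    def _update_intercept(self, name: str, disease: int) -> None:
        if self.cfg.prior_only:
            # flat prior: any proposal accepted; random walk is improper, skip
            return

        def ratio(d_):
            dlt = np.full(self.n, d_)
            return float(np.sum(self._lik_delta_vec(disease, dlt, slice(None)))), None

        def apply(d_, _):
            setattr(self.state, name, getattr(self.state, name) + d_)
            self.logtheta[disease] = self.logtheta[disease] + d_

        self._scalar_mh(name, ratio, apply)

    def _update_beta(self) -> None:
        x = self.x_cov if self.spec.model_id is ModelId.CM_SHR else self.state.u2
        vb = self.hp.beta_prior_var
        b = self.state.beta

        def ratio(d_):
            dprior = -0.5 * ((b + d_) ** 2 - b**2) / vb
            if self.cfg.prior_only:
                return dprior, None
            dlt = d_ * x
            return dprior + float(np.sum(self._lik_delta_vec(1, dlt, slice(None)))), dlt

        def apply(d_, dlt):
            self.state.beta = b + d_
            if dlt is not None:
                self.logtheta[1] = self.logtheta[1] + dlt

        self._scalar_mh("beta", ratio, apply)

    def _update_log_delta(self) -> None:
        ld = self.state.log_delta
        phi = self.state.phi
        kd = self.hp.kappa_delta

        def ratio(d_):
            ldn = ld + d_
            dprior = -0.5 * (ldn**2 - ld**2) / kd
            if self.cfg.prior_only:
                return dprior, None
            d1 = (np.exp(ldn) - np.exp(ld)) * phi
            d2 = (np.exp(-ldn) - np.exp(-ld)) * phi
            out = dprior
            out += float(np.sum(self._lik_delta_vec(1, d1, slice(None))))
            out += float(np.sum(self._lik_delta_vec(2, d2, slice(None))))
            return out, (d1, d2)

        def apply(d_, payload):
            self.state.log_delta = ld + d_
            if payload is not None:
                self.logtheta[1] = self.logtheta[1] + payload[0]
                self.logtheta[2] = self.logtheta[2] + payload[1]

        self._scalar_mh("log_delta", ratio, apply)

    def _field_lik_coefs(self, name: str) -> dict[int, float]:
        """Multiplier of this field in each disease's linear predictor."""
        mid = self.spec.model_id
        if name == "u1" or name == "v1":
            return {1: 1.0}
        if name == "v2":
            return {2: 1.0}
        if name == "u2":
            if mid is ModelId.CM_STRUCT:
                return {1: self.state.beta, 2: 1.0}
            return {2: 1.0}
        if name == "phi":
            return {1: self.state.beta1, 2: self.state.beta2}
        raise AssertionError(name)

    def _update_icar_field(self, name: str) -> None:
        if self.cfg.prior_only:
            return
        f = getattr(self.state, name)
        tau = getattr(self.state, f"tau_{name}")
        coefs = self._field_lik_coefs(name)
        for k, (C, W_C) in enumerate(zip(self.colors, self.W_rows)):
            s = W_C @ f
            x = f[C]
            step = self.steps_field[name][C]
            xp = x + step * self.rng.standard_normal(len(C))
            dx0 = xp - x
            dlik = -0.5 * tau * (self.deg[C] * (xp**2 - x**2) - 2.0 * dx0 * s)
            for d, g in coefs.items():
                if d in self.diseases:
                    dlt = g * dx0
                    mu = self.eC[d][k] * np.exp(self.logtheta[d][C])
                    dlik = dlik + self.yC[d][k] * dlt - mu * np.expm1(dlt)
            acc = np.log(self.rng.uniform(size=len(C))) < dlik
            self.try_field[name][C] += 1
            self.acc_field[name][C] += acc
            dx = np.where(acc, xp - x, 0.0)
            f[C] += dx
            for d, g in coefs.items():
                if d in self.diseases:
                    self.logtheta[d][C] += g * dx

    def _update_v_field(self, name: str) -> None:
        f = getattr(self.state, name)
        tau = getattr(self.state, f"tau_{name}")
        d = 1 if name == "v1" else 2
        step = self.steps_field[name]
        xp = f + step * self.rng.standard_normal(self.n)
        dr = -0.5 * tau * (xp**2 - f**2)
        if d in self.diseases:
            dr = dr + self._lik_delta_vec(d, xp - f, slice(None))
        acc = np.log(self.rng.uniform(size=self.n)) < dr
        self.try_field[name] += 1
        self.acc_field[name] += acc
        dx = np.where(acc, xp - f, 0.0)
        f += dx
        if d in self.diseases:
            self.logtheta[d] += dx

    def _center_v_fields(self) -> None:
        """Translation Gibbs move between each v field and its intercept.

        The posterior along the line (alpha + c, v - c) is proportional to
        the v prior only (the likelihood depends on alpha + v, the intercept
        is flat), so c | rest ~ N(mean(v), 1/(n*tau_v)); sampling it keeps
        the chain exactly invariant while decorrelating the intercept from
        the v-field level.
        """
        st = self.state
        for name in self.spec.v_fields():
            alpha_name = "alpha1" if name == "v1" else "alpha2"
            v = getattr(st, name)
            tau = getattr(st, f"tau_{name}")
            c = float(self.rng.normal(v.mean(), 1.0 / np.sqrt(self.n * tau)))
            v -= c
            setattr(st, alpha_name, getattr(st, alpha_name) + c)
            # log theta is unchanged by construction

    def _update_beta_ridge(self) -> None:
        """Directional Metropolis move along (beta, alpha1) for the SHR model.

        The uncentred SHR covariate makes beta and alpha1 strongly
        anti-correlated; a proposal beta += eps, alpha1 -= eps*mean(x) moves
        along that ridge (equivalent to updating beta against the centred
        covariate) and is a symmetric-proposal Metropolis step.
        """
        x = self.x_cov
        xbar = float(x.mean())
        b = self.state.beta
        vb = self.hp.beta_prior_var

        def ratio(d_):
            dprior = -0.5 * ((b + d_) ** 2 - b**2) / vb
            dlt = d_ * (x - xbar)
            return dprior + float(np.sum(self._lik_delta_vec(1, dlt, slice(None)))), dlt

        def apply(d_, dlt):
            self.state.beta = b + d_
            self.state.alpha1 -= d_ * xbar
            self.logtheta[1] = self.logtheta[1] + dlt

        self._scalar_mh("beta_ridge", ratio, apply)

    def _mode_swap_scm(self) -> None:
        """Involutive Metropolis move between the two shared-loading modes.

        The shared-component posterior can have a minor mode with the sign of
        log delta flipped and the disease-specific fields absorbing the
        difference.  The deterministic proposal

            log_delta -> -log_delta,
            u1 -> u1 + (delta - 1/delta) * phi,
            u2 -> u2 - (delta - 1/delta) * phi

        leaves both linear predictors exactly invariant (unit Jacobian,
        involution), so the acceptance ratio reduces to the ICAR prior ratio
        of the sheared fields; the log-delta prior is symmetric.  This lets
        chains hop between modes instead of sticking in one.
        """
        st = self.state
        from .icar_prior import pairwise_ss

        shift = (st.beta1 - st.beta2) * st.phi
        u1p = st.u1 + shift
        u2p = st.u2 - shift
        logr = -0.5 * st.tau_u1 * (
            pairwise_ss(u1p, self.graph) - pairwise_ss(st.u1, self.graph)
        ) - 0.5 * st.tau_u2 * (
            pairwise_ss(u2p, self.graph) - pairwise_ss(st.u2, self.graph)
        )
        if np.log(self.rng.uniform()) < logr:
            st.log_delta = -st.log_delta
            st.u1, st.u2 = u1p, u2p

    def _recenter_fields(self) -> None:
        st = self.state
        mid = self.spec.model_id
        for name in self.spec.icar_fields():
            f, gbar = recenter(getattr(st, name), self.graph)
            setattr(st, name, f)
            if name == "u1":
                st.alpha1 += gbar
            elif name == "u2":
                st.alpha2 += gbar
                if mid is ModelId.CM_STRUCT:
                    st.alpha1 += st.beta * gbar
            else:  # phi
                st.alpha1 += st.beta1 * gbar
                st.alpha2 += st.beta2 * gbar

    def _update_precisions(self) -> None:
        hp, st = self.hp, self.state
        for name in self.spec.icar_fields():
            if self.cfg.prior_only:
                # field removed from the model in prior-only mode: sample the prior
                setattr(st, f"tau_{name}",
                        float(self.rng.gamma(hp.tau_gamma_a, 1.0 / hp.tau_gamma_b)))
                continue
            fld = IcarField(getattr(st, name), self.graph, getattr(st, f"tau_{name}"))
            shape, rate = tau_posterior_params(fld, hp.tau_gamma_a, hp.tau_gamma_b)
            setattr(st, f"tau_{name}", float(self.rng.gamma(shape, 1.0 / rate)))
        for name in self.spec.v_fields():
            v = getattr(st, name)
            shape = hp.tau_gamma_a + 0.5 * self.n
            rate = hp.tau_gamma_b + 0.5 * float(v @ v)
            setattr(st, f"tau_{name}", float(self.rng.gamma(shape, 1.0 / rate)))

    # -- sweep ---------------------------------------------------------------

    def sweep(self, adapting: bool, sweep_index: int) -> None:
        st = self.state
        if not self.cfg.prior_only:
            self._refresh_logtheta()
        self._update_intercept("alpha1", 1)
        if st.alpha2 is not None:
            self._update_intercept("alpha2", 2)
        if st.beta is not None:
            self._update_beta()
        if st.log_delta is not None:
            self._update_log_delta()
        for name in self.spec.icar_fields():
            self._update_icar_field(name)
        for name in self.spec.v_fields():
            self._update_v_field(name)
        if not self.cfg.prior_only:
            self._center_v_fields()
            if self.spec.model_id is ModelId.CM_SHR:
                self._update_beta_ridge()
            if self.spec.model_id is ModelId.SCM:
                self._mode_swap_scm()
            self._recenter_fields()
            self._refresh_logtheta()
        if not self.cfg.fix_precisions:
            self._update_precisions()
        if adapting and (sweep_index + 1) % self.cfg.adapt_interval == 0:
            self._adapt()
        if not np.isfinite(st.alpha1):
            raise RuntimeError(
                f"chain diverged at sweep {sweep_index}: "
                f"state={ {k: getattr(st, k) for k in self.spec.scalar_params()} }"
            )


def _chain_rng(seed: int, chain_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, chain_index]))


def run_chain(
    spec: ModelSpec,
    table: AreaTable,
    graph: AdjacencyGraph,
    config: SamplerConfig,
    chain_index: int = 0,
    init: ParamState | None = None,
) -> dict:
    """Run one chain; returns per-chain draws as arrays.

    The returned dict maps scalar names to (n_draws,) arrays, field names to
    (n_draws, n) arrays (if stored), plus ``deviance`` and per-disease
    ``mean_log_theta``.
    """
    rng = _chain_rng(config.seed, chain_index)
    if init is None:
        init = initial_state(spec, table, graph, rng, overdispersed=config.n_chains > 1)
    runner = _ChainRunner(spec, table, graph, config, rng, init)
    n_keep = config.n_iter // config.thin
    scalars = {k: np.empty(n_keep) for k in spec.scalar_params() + spec.precision_params()}
    fields_: dict[str, np.ndarray] = {}
    if config.store_fields:
        fields_ = {k: np.empty((n_keep, graph.n)) for k in spec.field_params()}
    deviance = np.empty(n_keep)
    mlt = {d: np.zeros(graph.n) for d in runner.diseases}

    for t in range(config.n_burnin):
        runner.sweep(adapting=True, sweep_index=t)
    kept = 0
    for t in range(config.n_iter):
        runner.sweep(adapting=False, sweep_index=config.n_burnin + t)
        if (t + 1) % config.thin == 0:
            st = runner.state
            for k in spec.scalar_params() + spec.precision_params():
                scalars[k][kept] = getattr(st, k)
            for k in fields_:
                fields_[k][kept] = getattr(st, k)
            deviance[kept] = runner.deviance() if runner.diseases else np.nan
            for d in runner.diseases:
                mlt[d] += runner.logtheta[d]
            kept += 1
    if kept:
        for d in mlt:
            mlt[d] /= kept
    return {"scalars": scalars, "fields": fields_, "deviance": deviance,
            "mean_log_theta": mlt}


def run_chains(
    spec: ModelSpec,
    table: AreaTable,
    graph: AdjacencyGraph,
    config: SamplerConfig,
) -> PosteriorDraws:
    """Run ``config.n_chains`` chains with deterministically derived seeds."""
    chains = [
        run_chain(spec, table, graph, config, chain_index=c)
        for c in range(config.n_chains)
    ]
    scalars = {
        k: np.stack([ch["scalars"][k] for ch in chains])
        for k in chains[0]["scalars"]
    }
    fields_ = {
        k: np.stack([ch["fields"][k] for ch in chains]) for k in chains[0]["fields"]
    }
    deviance = np.stack([ch["deviance"] for ch in chains])
    mlt: dict[int, np.ndarray] = {}
    for d in chains[0]["mean_log_theta"]:
        mlt[d] = np.mean([ch["mean_log_theta"][d] for ch in chains], axis=0)
    return PosteriorDraws(
        model=spec,
        scalars=scalars,
        fields=fields_,
        deviance=deviance,
        mean_log_theta=mlt,
        n_areas=graph.n,
        config=config,
    )
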