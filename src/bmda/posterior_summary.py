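"""Posterior summaries: relative risks, DIC, component ratios, diagnostics.

DIC follows the standard deviance decomposition: Dbar is the posterior mean
deviance, D(theta_bar) evaluates the deviance at the posterior mean of each
area's linear predictor (plug-in on the log relative-risk scale), the
effective parameter count is pD = Dbar - D(theta_bar), and DIC = Dbar + pD.
The deviance includes the log(y!) terms, matching the WinBUGS convention.

The component ratio measures, draw by draw, the share of an outcome's
spatial log-risk variation across areas that the named model component
carries: with component c_i (beta*SHR2, beta1*u2, or beta1*phi) and residual
fields u + v, ratio = Var_areas(c) / Var_areas(c + u + v); the posterior
median and (5%, 95%) interval of that ratio are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .areal_data import AdjacencyGraph, AreaTable
from .model_specs import ModelId, ModelSpec, poisson_log_lik
from .sampler import PosteriorDraws

__all__ = [
    "DicResult",
    "ComponentRatio",
    "McError",
    "FitResult",
    "summarize",
    "log_theta_draws",
    "compute_dic",
    "component_ratio",
    "gelman_rubin",
    "mc_error",
    "fit_result",
    "export_results",
    "intercept_only_dic",
]

DEFAULT_PROBS = (0.05, 0.5, 0.95)
DEFAULT_BREAKS = (0.5, 1.0, 1.5)
MC_ERROR_RULE = 0.05  # mc error acceptable below 5% of the posterior SD


@dataclass
class DicResult:
    dbar: float
    d_at_mean: float
    pd: float
    dic: float


@dataclass
class ComponentRatio:
    median: float
    q05: float
    q95: float
    n_missing: int = 0


@dataclass
class McError:
    se: float
    ratio: float
    ok: bool


@dataclass
class FitResult:
    """Everything a fit reports: summaries, DIC, ratios, diagnostics."""

    model: ModelSpec
    scalar_summary: pd.DataFrame
    area_summary: pd.DataFrame | None
    dic: DicResult
    component_ratios: dict[int, ComponentRatio]
    diagnostics: pd.DataFrame
    n_draws: int
    n_chains: int

    def converged(self, rhat_limit: float = 1.1) -> bool:
        ok_rhat = (self.diagnostics["rhat"] < rhat_limit).all()
        ok_mc = self.diagnostics["mc_ok"].all()
        return bool(ok_rhat and ok_mc)


def _pooled_matrix(draws: PosteriorDraws, name: str) -> np.ndarray:
    """Pooled (T_total, n) field draws."""
    f = draws.field(name)
    return f.reshape(-1, f.shape[-1])


def log_theta_draws(
    draws: PosteriorDraws, table: AreaTable, disease: int
) -> np.ndarray:
    """Reconstruct pooled (T, n) draws of the log relative risk."""
    spec = draws.model
    mid = spec.model_id
    if mid is ModelId.CM_SHR:
        if disease != 1:
            raise ValueError("the SHR covariate model has disease 1 only")
        return (
            draws.pooled("alpha1")[:, None]
            + draws.pooled("beta")[:, None] * table.shr(2)[None, :]
            + _pooled_matrix(draws, "u1")
            + _pooled_matrix(draws, "v1")
        )
    if mid is ModelId.CM_STRUCT:
        if disease == 1:
            return (
                draws.pooled("alpha1")[:, None]
                + draws.pooled("beta")[:, None] * _pooled_matrix(draws, "u2")
                + _pooled_matrix(draws, "u1")
                + _pooled_matrix(draws, "v1")
            )
        return (
            draws.pooled("alpha2")[:, None]
            + _pooled_matrix(draws, "u2")
            + _pooled_matrix(draws, "v2")
        )
    # SCM
    ld = draws.pooled("log_delta")
    if disease == 1:
        return (
            draws.pooled("alpha1")[:, None]
            + np.exp(ld)[:, None] * _pooled_matrix(draws, "phi")
            + _pooled_matrix(draws, "u1")
            + _pooled_matrix(draws, "v1")
        )
    return (
        draws.pooled("alpha2")[:, None]
        + np.exp(-ld)[:, None] * _pooled_matrix(draws, "phi")
        + _pooled_matrix(draws, "u2")
        + _pooled_matrix(draws, "v2")
    )


def summarize(
    draws: PosteriorDraws,
    table: AreaTable | None = None,
    probs: tuple[float, ...] = DEFAULT_PROBS,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pooled-chain quantile summaries.

    Returns (scalar table, per-area table).  Scalars include every retained
    parameter plus the variances 1/tau.  The per-area table (posterior
    relative-risk quantiles per disease) requires field draws and a table; it
    is None otherwise.
    """
    if draws.n_draws == 0:
        raise ValueError("empty draws")
    qlab = [f"q{int(round(p * 100)):02d}" for p in probs]
    rows = {}
    for name in draws.parameter_names():
        x = draws.pooled(name)
        rows[name] = [*np.quantile(x, probs), x.mean(), x.std(ddof=1)]
        if name.startswith("tau_"):
            s2 = 1.0 / x
            rows["sigma2_" + name[4:]] = [*np.quantile(s2, probs), s2.mean(), s2.std(ddof=1)]
    scalar_df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[*qlab, "mean", "sd"]
    )
    area_df = None
    if table is not None and draws.fields:
        per_disease = []
        diseases = draws.model.diseases
        for d in diseases:
            theta = np.exp(log_theta_draws(draws, table, d))
            q = np.quantile(theta, probs, axis=0)
            per_disease.append(
                pd.DataFrame(
                    {f"rr{d}_{lab}": q[k] for k, lab in enumerate(qlab)},
                    index=table.area_id,
                )
            )
        area_df = pd.concat(per_disease, axis=1)
        area_df.index.name = "area_id"
    return scalar_df, area_df


def compute_dic(
    draws: PosteriorDraws,
    spec: ModelSpec,
    table: AreaTable,
    graph: AdjacencyGraph | None = None,
) -> DicResult:
    """DIC from stored per-draw deviances and the plug-in deviance."""
    dev = draws.deviance.reshape(-1)
    dev = dev[np.isfinite(dev)]
    if dev.size == 0:
        raise ValueError("no deviance draws stored (prior-only run?)")
    dbar = float(dev.mean())
    d_hat = 0.0
    for d in spec.diseases:
        d_hat += -2.0 * poisson_log_lik(
            table.y(d), table.e(d), draws.mean_log_theta[d]
        )
    pd_ = dbar - d_hat
    if pd_ < 0:
        import warnings

        warnings.warn(f"negative effective parameter count pD={pd_:.3f}")
    return DicResult(dbar=dbar, d_at_mean=float(d_hat), pd=float(pd_), dic=dbar + pd_)


def component_ratio(
    draws: PosteriorDraws,
    spec: ModelSpec,
    table: AreaTable,
    disease: int = 1,
) -> ComponentRatio:
    """Posterior share of log-risk variation carried by the named component."""
    mid = spec.model_id
    if mid is ModelId.CM_SHR:
        comp = draws.pooled("beta")[:, None] * table.shr(2)[None, :]
        resid = _pooled_matrix(draws, "u1") + _pooled_matrix(draws, "v1")
    elif mid is ModelId.CM_STRUCT:
        if disease != 1:
            raise ValueError("the structured covariate model defines a ratio for disease 1")
        comp = draws.pooled("beta")[:, None] * _pooled_matrix(draws, "u2")
        resid = _pooled_matrix(draws, "u1") + _pooled_matrix(draws, "v1")
    else:
        load = np.exp(draws.pooled("log_delta") * (1 if disease == 1 else -1))
        comp = load[:, None] * _pooled_matrix(draws, "phi")
        if disease == 1:
            resid = _pooled_matrix(draws, "u1") + _pooled_matrix(draws, "v1")
        else:
            resid = _pooled_matrix(draws, "u2") + _pooled_matrix(draws, "v2")
    var_c = comp.var(axis=1, ddof=1)
    var_tot = (comp + resid).var(axis=1, ddof=1)
    ok = var_tot > 0
    n_missing = int((~ok).sum())
    ratio = var_c[ok] / var_tot[ok]
    if ratio.size == 0:
        raise ValueError("total variance is zero in every draw; ratio undefined")
    q05, med, q95 = np.quantile(ratio, DEFAULT_PROBS)
    return ComponentRatio(median=float(med), q05=float(q05), q95=float(q95),
                          n_missing=n_missing)


def _as_chain_matrix(draws, parameter: str | None) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        return draws.get(parameter)
    x = np.atleast_2d(np.asarray(draws, dtype=float))
    return x


def gelman_rubin(draws, parameter: str | None = None) -> float:
    """Potential scale reduction factor from between/within chain variances."""
    x = _as_chain_matrix(draws, parameter)
    k, m = x.shape
    if k < 2:
        raise ValueError("PSRF requires at least 2 chains")
    if m < 10:
        raise ValueError("PSRF requires at least 10 draws per chain")
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = m * chain_means.var(ddof=1)
    var_hat = (m - 1) / m * w + b / m
    if w == 0:
        return 1.0 if b == 0 else np.inf
    return float(np.sqrt(var_hat / w))


def mc_error(draws, parameter: str | None = None) -> McError:
    """Batch-means Monte Carlo standard error with floor(sqrt(m)) batches.

    Returns the SE of the posterior mean, its ratio to the posterior SD, and
    a flag for the "MC error below 5% of the posterior SD" rule.
    """
    x = _as_chain_matrix(draws, parameter)
    k, m = x.shape
    if m < 20:
        raise ValueError("MC error requires at least 20 retained draws per chain")
    nb = int(np.sqrt(m))
    size = m // nb
    se2 = 0.0
    for c in range(k):
        bm = x[c, : nb * size].reshape(nb, size).mean(axis=1)
        se2 += bm.var(ddof=1) / nb
    se = float(np.sqrt(se2) / k)
    sd = float(x.reshape(-1).std(ddof=1))
    ratio = se / sd if sd > 0 else 0.0
    return McError(se=se, ratio=float(ratio), ok=bool(ratio < MC_ERROR_RULE))


def fit_result(
    draws: PosteriorDraws,
    spec: ModelSpec,
    table: AreaTable,
    graph: AdjacencyGraph | None = None,
    probs: tuple[float, ...] = DEFAULT_PROBS,
) -> FitResult:
    """Assemble summaries, DIC, component ratios and diagnostics for a fit."""
    scalar_df, area_df = summarize(draws, table, probs)
    dic = compute_dic(draws, spec, table, graph)
    ratios: dict[int, ComponentRatio] = {}
    if draws.fields:
        ratios[1] = component_ratio(draws, spec, table, disease=1)
        if spec.model_id is ModelId.SCM:
            ratios[2] = component_ratio(draws, spec, table, disease=2)
    diag_rows = {}
    for name in draws.parameter_names():
        x = draws.get(name)
        entry = {"sd": float(x.std(ddof=1))}
        entry["rhat"] = gelman_rubin(x) if draws.n_chains > 1 else np.nan
        me = mc_error(x)
        entry["mc_error"] = me.se
        entry["mc_ratio"] = me.ratio
        entry["mc_ok"] = me.ok
        diag_rows[name] = entry
    diagnostics = pd.DataFrame.from_dict(diag_rows, orient="index")
    return FitResult(
        model=spec,
        scalar_summary=scalar_df,
        area_summary=area_df,
        dic=dic,
        component_ratios=ratios,
        diagnostics=diagnostics,
        n_draws=draws.n_draws,
        n_chains=draws.n_chains,
    )


def _class_bin(rr: np.ndarray, breaks: tuple[float, ...]) -> list[str]:
    labels = [f"<{breaks[0]:g}"]
    labels += [f"{lo:g}-{hi:g}" for lo, hi in zip(breaks[:-1], breaks[1:])]
    labels += [f">{breaks[-1]:g}"]
    idx = np.digitize(rr, breaks)
    return [labels[i] for i in idx]


def export_results(
    fit: FitResult,
    table: AreaTable,
    out_dir: str | Path,
    breaks: tuple[float, ...] = DEFAULT_BREAKS,
) -> dict[str, Path]:
    """Write the per-area CSV and scalar JSON summaries; returns the paths.

    The per-area CSV carries observed data, SHRs, posterior RR median and
    (5%, 95%) interval per disease, and a map-ready class-bin column per
    disease using the given relative-risk breaks.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = table.to_frame().set_index("area_id")
    if fit.area_summary is not None:
        df = df.join(fit.area_summary)
        for d in fit.model.diseases:
            med = fit.area_summary[f"rr{d}_q50"].to_numpy()
            df[f"rr{d}_class"] = _class_bin(med, breaks)
    area_path = out / "area_summaries.csv"
    df.to_csv(area_path)

    payload = {
        "model": fit.model.to_config(),
        "n_chains": fit.n_chains,
        "n_draws": fit.n_draws,
        "dic": {"dbar": fit.dic.dbar, "d_at_mean": fit.dic.d_at_mean,
                "pd": fit.dic.pd, "dic": fit.dic.dic},
        "component_ratio": {
            str(d): {"median": r.median, "q05": r.q05, "q95": r.q95,
                     "n_missing": r.n_missing}
            for d, r in fit.component_ratios.items()
        },
        "scalar_summary": fit.scalar_summary.round(10).to_dict(orient="index"),
        "diagnostics": fit.diagnostics.round(10).to_dict(orient="index"),
        "class_breaks": list(breaks),
    }
    json_path = out / "fit_summary.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"area_csv": area_path, "summary_json": json_path}


def intercept_only_dic(
    table: AreaTable,
    diseases: tuple[int, ...],
    rng: np.random.Generator,
    n_draws: int = 4000,
) -> DicResult:
    """DIC of the intercept-only Poisson baseline, via the exact posterior.

    Under a flat prior on alpha with Y_i ~ Poisson(E_i * e^alpha), the
    posterior of lambda = e^alpha is Gamma(sum Y, sum E), so deviance draws
    are available without MCMC.  The plug-in uses the posterior mean of alpha
    (log scale), matching the hierarchical fits' plug-in convention.
    """
    from scipy.special import gammaln

    dbar = 0.0
    d_hat = 0.0
    for d in diseases:
        y = np.asarray(table.y(d), dtype=float)
        e = np.asarray(table.e(d), dtype=float)
        lam = rng.gamma(y.sum(), 1.0 / e.sum(), size=n_draws)
        const = float(np.sum(y * np.log(e) - gammaln(y + 1.0)))
        dev = -2.0 * (const + y.sum() * np.log(lam) - lam * e.sum())
        dbar += float(dev.mean())
        alpha_bar = float(np.mean(np.log(lam)))
        d_hat += -2.0 * poisson_log_lik(y, e, np.full(len(y), alpha_bar))
    pd_ = dbar - d_hat
    return DicResult(dbar=dbar, d_at_mean=d_hat, pd=pd_, dic=dbar + pd_)
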