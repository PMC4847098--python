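"""The three joint model structures, their parameters, and the log posterior.

All three models share the first level  Y_di ~ Poisson(E_di * theta_di)  and
differ in the log relative-risk predictor:

* ``CM_SHR`` (covariate model on the raw SHR; disease-1 likelihood only):
      log theta_1i = alpha1 + beta * SHR_2i + u_1i + v_1i
* ``CM_STRUCT`` (covariate model on disease 2's structured effect):
      log theta_1i = alpha1 + beta1 * u_2i + u_1i + v_1i
      log theta_2i = alpha2 + u_2i + v_2i
* ``SCM`` (shared component model):
      log theta_1i = alpha1 + delta   * phi_i + u_1i + v_1i
      log theta_2i = alpha2 + (1/delta) * phi_i + u_2i + v_2i
  with the shared-field loadings constrained to beta1 * beta2 = 1 through the
  parameterization delta = exp(log_delta).

Priors: flat intercepts; beta ~ N(0, 1000); log delta ~ N(0, kappa_delta);
u/phi fields ICAR(tau); v fields i.i.d. N(0, 1/tau_v); every precision
tau ~ Gamma(0.001, 0.001).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .areal_data import AdjacencyGraph, AreaTable
from .icar_prior import IcarField, icar_log_density_unnorm

__all__ = [
    "ModelId",
    "HyperParams",
    "ModelSpec",
    "ParamState",
    "linear_predictor",
    "poisson_log_lik",
    "joint_log_posterior",
]


class ModelId(str, enum.Enum):
    CM_SHR = "cm-shr"        # Model 1
    CM_STRUCT = "cm-struct"  # Model 2
    SCM = "scm"              # Model 3

    @classmethod
    def parse(cls, value: "ModelId | str") -> "ModelId":
        if isinstance(value, cls):
            return value
        key = str(value).lower().replace("_", "-")
        for m in cls:
            if m.value == key:
                return m
        raise ValueError(f"unknown model id {value!r}; expected one of "
                         f"{[m.value for m in cls]}")


@dataclass
class HyperParams:
    """Hyperprior constants shared by all three models."""

    tau_gamma_a: float = 0.001
    tau_gamma_b: float = 0.001
    beta_prior_var: float = 1000.0
    kappa_delta: float = 5.88  # prior variance of log delta

    def __post_init__(self) -> None:
        for f_ in fields(self):
            if not getattr(self, f_.name) > 0:
                raise ValueError(f"{f_.name} must be strictly positive")


@dataclass
class ModelSpec:
    """Which model structure to fit, plus its hyperprior constants."""

    model_id: ModelId
    hyper: HyperParams = field(default_factory=HyperParams)

    def __post_init__(self) -> None:
        self.model_id = ModelId.parse(self.model_id)

    @property
    def n_diseases(self) -> int:
        return 1 if self.model_id is ModelId.CM_SHR else 2

    @property
    def diseases(self) -> tuple[int, ...]:
        return (1,) if self.model_id is ModelId.CM_SHR else (1, 2)

    def scalar_params(self) -> list[str]:
        if self.model_id is ModelId.CM_SHR:
            return ["alpha1", "beta"]
        if self.model_id is ModelId.CM_STRUCT:
            return ["alpha1", "alpha2", "beta"]
        return ["alpha1", "alpha2", "log_delta"]

    def field_params(self) -> list[str]:
        if self.model_id is ModelId.CM_SHR:
            return ["u1", "v1"]
        if self.model_id is ModelId.CM_STRUCT:
            return ["u1", "u2", "v1", "v2"]
        return ["u1", "u2", "phi", "v1", "v2"]

    def icar_fields(self) -> list[str]:
        return [f_ for f_ in self.field_params() if f_ in ("u1", "u2", "phi")]

    def v_fields(self) -> list[str]:
        return [f_ for f_ in self.field_params() if f_ in ("v1", "v2")]

    def precision_params(self) -> list[str]:
        return [f"tau_{f_}" for f_ in self.field_params()]

    def to_config(self) -> dict:
        return {
            "model": self.model_id.value,
            "hyper": {f_.name: getattr(self.hyper, f_.name) for f_ in fields(HyperParams)},
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "ModelSpec":
        return cls(ModelId.parse(cfg["model"]), HyperParams(**cfg.get("hyper", {})))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_config(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelSpec":
        return cls.from_config(json.loads(Path(path).read_text()))


@dataclass
class ParamState:
    """One point in parameter space; only the model's active fields are set."""

    alpha1: float | None = None
    alpha2: float | None = None
    beta: float | None = None        # Model 1 beta / Model 2 beta1
    log_delta: float | None = None   # Model 3; beta1=exp(ld), beta2=exp(-ld)
    u1: np.ndarray | None = None
    u2: np.ndarray | None = None
    phi: np.ndarray | None = None
    v1: np.ndarray | None = None
    v2: np.ndarray | None = None
    tau_u1: float | None = None
    tau_u2: float | None = None
    tau_phi: float | None = None
    tau_v1: float | None = None
    tau_v2: float | None = None

    @property
    def beta1(self) -> float:
        """Shared-component loading for disease 1 (= delta)."""
        assert self.log_delta is not None
        return float(np.exp(self.log_delta))

    @property
    def beta2(self) -> float:
        """Shared-component loading for disease 2 (= 1/delta)."""
        assert self.log_delta is not None
        return float(np.exp(-self.log_delta))

    def copy(self) -> "ParamState":
        out = ParamState()
        for f_ in fields(self):
            v = getattr(self, f_.name)
            setattr(out, f_.name, v.copy() if isinstance(v, np.ndarray) else v)
        return out

    def check_active(self, spec: ModelSpec) -> None:
        active = set(spec.scalar_params() + spec.field_params() + spec.precision_params())
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if f_.name in active and v is None:
                raise ValueError(f"parameter {f_.name} required by {spec.model_id} is unset")
            if f_.name not in active and v is not None:
                raise ValueError(f"parameter {f_.name} is inactive under {spec.model_id}")


def linear_predictor(
    spec: ModelSpec, state: ParamState, table: AreaTable, disease: int
) -> np.ndarray:
    """The model's log relative-risk vector for one disease."""
    mid = spec.model_id
    if mid is ModelId.CM_SHR:
        if disease != 1:
            raise ValueError("the SHR covariate model has a disease-1 likelihood only")
        return state.alpha1 + state.beta * table.shr(2) + state.u1 + state.v1
    if mid is ModelId.CM_STRUCT:
        if disease == 1:
            return state.alpha1 + state.beta * state.u2 + state.u1 + state.v1
        return state.alpha2 + state.u2 + state.v2
    # SCM
    if disease == 1:
        return state.alpha1 + state.beta1 * state.phi + state.u1 + state.v1
    return state.alpha2 + state.beta2 * state.phi + state.u2 + state.v2


def poisson_log_lik(y: np.ndarray, e: np.ndarray, log_theta: np.ndarray) -> float:
    """Poisson log likelihood sum_i log Pois(y_i; e_i * theta_i), log(y!) included."""
    y = np.asarray(y, dtype=float)
    e = np.asarray(e, dtype=float)
    log_theta = np.asarray(log_theta, dtype=float)
    if not (y.shape == e.shape == log_theta.shape):
        raise ValueError("y, e and log_theta must have equal length")
    if not (e > 0).all():
        raise ValueError("expected counts must be strictly positive")
    log_mu = np.log(e) + log_theta
    return float(np.sum(y * log_mu - np.exp(log_mu) - gammaln(y + 1.0)))


def _gamma_logpdf_unnorm(tau: float, a: float, b: float) -> float:
    if not tau > 0:
        raise ValueError("precision must be strictly positive")
    return (a - 1.0) * np.log(tau) - b * tau


def joint_log_posterior(
    spec: ModelSpec, state: ParamState, table: AreaTable, graph: AdjacencyGraph
) -> float:
    """Log posterior density up to an additive constant.

    Sum of Poisson log likelihood(s), ICAR kernels, i.i.d. normal terms for
    the v fields, the coefficient priors and Gamma priors on all active
    precisions.  Flat intercepts contribute nothing.  Normalizing constants
    not involving parameters are dropped; differences between states are
    exact.
    """
    state.check_active(spec)
    hp = spec.hyper
    lp = 0.0
    for d in spec.diseases:
        lp += poisson_log_lik(table.y(d), table.e(d), linear_predictor(spec, state, table, d))
    for name in spec.icar_fields():
        tau = getattr(state, f"tau_{name}")
        lp += icar_log_density_unnorm(IcarField(getattr(state, name), graph, tau))
    for name in spec.v_fields():
        tau = getattr(state, f"tau_{name}")
        if not tau > 0:
            raise ValueError(f"tau_{name} must be strictly positive")
        v = getattr(state, name)
        lp += 0.5 * graph.n * np.log(tau) - 0.5 * tau * float(v @ v)
    if spec.model_id in (ModelId.CM_SHR, ModelId.CM_STRUCT):
        lp += -0.5 * state.beta**2 / hp.beta_prior_var
    else:
        lp += -0.5 * state.log_delta**2 / hp.kappa_delta
    for name in spec.precision_params():
        lp += _gamma_logpdf_unnorm(getattr(state, name), hp.tau_gamma_a, hp.tau_gamma_b)
    return float(lp)
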