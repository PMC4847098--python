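"""Intrinsic conditional autoregressive (ICAR) prior machinery.

The ICAR prior is the improper Gaussian Markov random field

    p(f | tau)  ∝  tau^((n-G)/2) * exp( -tau/2 * sum_{i~j} (f_i - f_j)^2 )

with the pairwise sum over unique undirected edges of the adjacency graph and
G the number of connected components (the kernel's rank deficiency is exactly
G: one flat direction per component).  Each area's full conditional is normal
around the mean of its neighbours with variance 1/(tau * m_i), m_i the
neighbour count.  The field is identified by a per-component sum-to-zero
constraint; isolated nodes carry no spatial information and are pinned at 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .areal_data import AdjacencyGraph

__all__ = [
    "IcarField",
    "pairwise_ss",
    "icar_log_density_unnorm",
    "icar_full_conditional",
    "tau_posterior_params",
    "sample_icar_field",
    "recenter",
]

# relative eigenvalue cutoff separating the Laplacian null space
_NULL_TOL = 1e-9


@dataclass
class IcarField:
    """A realization of an ICAR field together with its graph and precision."""

    values: np.ndarray
    graph: AdjacencyGraph
    precision: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.graph.n,):
            raise ValueError(
                f"field length {self.values.shape} != graph size {self.graph.n}"
            )
        if not self.precision > 0:
            raise ValueError("precision must be strictly positive")


def pairwise_ss(values: np.ndarray, graph: AdjacencyGraph) -> float:
    """Sum over unique edges of squared differences, f' L f."""
    f = np.asarray(values, dtype=float)
    if f.shape != (graph.n,):
        raise ValueError(f"field length {f.shape} != graph size {graph.n}")
    return float(f @ (graph.laplacian() @ f))


def icar_log_density_unnorm(field: IcarField) -> float:
    """Unnormalized ICAR log density ((n-G)/2) log tau - (tau/2) SS."""
    n, g = field.graph.n, field.graph.n_components
    ss = pairwise_ss(field.values, field.graph)
    return 0.5 * (n - g) * np.log(field.precision) - 0.5 * field.precision * ss


def icar_full_conditional(field: IcarField, i: int) -> tuple[float, float]:
    """Full conditional of f_i | f_-i: (neighbour mean, 1/(tau*m_i))."""
    nb = field.graph.neighbours[i]
    if len(nb) == 0:
        raise ValueError(
            f"node {i} is isolated: its ICAR full conditional is undefined "
            "(sampler policy pins isolated nodes at 0)"
        )
    mean = float(field.values[nb].mean())
    var = 1.0 / (field.precision * len(nb))
    return mean, var


def tau_posterior_params(
    field: IcarField, a: float, b: float
) -> tuple[float, float]:
    """Conjugate Gamma update for the ICAR precision.

    With prior tau ~ Gamma(a, b) (rate parameterization), the full
    conditional is Gamma(a + (n-G)/2, b + SS/2).
    """
    if not (a > 0 and b > 0):
        raise ValueError("Gamma hyperparameters must be positive")
    n, g = field.graph.n, field.graph.n_components
    ss = pairwise_ss(field.values, field.graph)
    return a + 0.5 * (n - g), b + 0.5 * ss


def _laplacian_eig(graph: AdjacencyGraph) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the graph Laplacian, cached on the graph."""
    cached = getattr(graph, "_lap_eig", None)
    if cached is None:
        lam, vec = np.linalg.eigh(graph.laplacian().toarray())
        cached = (lam, vec)
        graph._lap_eig = cached  # type: ignore[attr-defined]
    return cached


def sample_icar_field(
    graph: AdjacencyGraph, tau: float, rng: np.random.Generator
) -> IcarField:
    """Exact draw from the intrinsic Gaussian on the constraint subspace.

    Independent normals with variance 1/(tau*lambda_k) are drawn on Laplacian
    eigenvectors with lambda_k > 0 and zero weight on the null space, so each
    connected component sums to zero and isolated nodes are exactly 0.
    """
    if not tau > 0:
        raise ValueError("tau must be strictly positive")
    lam, vec = _laplacian_eig(graph)
    scale_max = max(lam.max(initial=0.0), 1.0)
    pos = lam > _NULL_TOL * scale_max
    if not pos.any():
        import warnings

        warnings.warn("graph has no edges; ICAR field is identically zero")
        return IcarField(np.zeros(graph.n), graph, tau)
    z = rng.standard_normal(int(pos.sum()))
    coef = z / np.sqrt(tau * lam[pos])
    values = vec[:, pos] @ coef
    # snap per-component means to exactly zero against rounding
    values = recenter(values, graph)[0]
    return IcarField(values, graph, tau)


def recenter(values: np.ndarray, graph: AdjacencyGraph) -> tuple[np.ndarray, float]:
    """Project a field onto per-component sum-to-zero; return (field, global mean).

    The global mean (over all areas) is returned so callers can absorb it into
    an intercept; for a connected graph the projection is exactly a constant
    shift by that mean.  Isolated nodes are set to 0.
    """
    f = np.asarray(values, dtype=float).copy()
    gbar = float(f.mean()) if graph.n else 0.0
    for c in range(graph.n_components):
        mask = graph.components == c
        f[mask] -= f[mask].mean()
    f[graph.degrees == 0] = 0.0
    return f, gbar
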