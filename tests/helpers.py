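"""Shared builders for tests: small tables, graphs and random valid states."""

from __future__ import annotations

import numpy as np

from bmda import AdjacencyGraph, AreaTable, ModelId, ModelSpec, ParamState, standardize


def chain_graph(n: int) -> AdjacencyGraph:
    return AdjacencyGraph.from_edges(n, [(i, i + 1) for i in range(n - 1)])


def small_table(n: int, rng: np.random.Generator, mean_count: float = 50.0) -> AreaTable:
    """A standardized two-disease table with heterogeneous populations."""
    pop = rng.uniform(0.5, 2.0, size=n) * 10_000
    rate = mean_count / 10_000
    y1 = rng.poisson(pop * rate * rng.uniform(0.5, 1.5, size=n)) + 1
    y2 = rng.poisson(pop * rate * rng.uniform(0.5, 1.5, size=n)) + 1
    return standardize(AreaTable(
        area_id=[f"a{i}" for i in range(n)], population=pop, y1=y1, y2=y2,
    ))


def random_state(
    spec: ModelSpec,
    table: AreaTable,
    graph: AdjacencyGraph,
    rng: np.random.Generator,
) -> ParamState:
    """A random point in the model's parameter space (fields not recentred)."""
    n = graph.n
    st = ParamState()
    st.alpha1 = float(rng.normal(0, 0.3))
    if spec.model_id is not ModelId.CM_SHR:
        st.alpha2 = float(rng.normal(0, 0.3))
    if spec.model_id in (ModelId.CM_SHR, ModelId.CM_STRUCT):
        st.beta = float(rng.normal(0, 0.3))
    else:
        st.log_delta = float(rng.normal(0, 0.3))
    for name in spec.field_params():
        setattr(st, name, rng.normal(0, 0.3, size=n))
        setattr(st, f"tau_{name}", float(rng.uniform(0.5, 3.0)))
    return st


def all_sites(spec: ModelSpec, graph: AdjacencyGraph) -> list[tuple[str, int | None]]:
    sites: list[tuple[str, int | None]] = [(s, None) for s in spec.scalar_params()]
    for name in spec.field_params():
        for i in range(graph.n):
            if name in ("u1", "u2", "phi") and len(graph.neighbours[i]) == 0:
                continue  # isolated ICAR coordinates are pinned
            sites.append((name, i))
    return sites
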