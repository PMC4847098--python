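"""Areal count data: loading, validation, standardization and adjacency.

The central container is :class:`AreaTable`, one row per areal unit (e.g. a
sub-district) holding a population at risk and observed hospitalization
counts for up to two diseases.  Expected counts are produced by internal
(indirect) standardization on the pooled rate, and standardized
hospitalization ratios (SHR = observed / expected) are the maximum-likelihood
relative-risk estimates that the hierarchical models smooth.

Neighbourhood structure is supplied externally as a GAL spatial-weights file
or a two-column edge list; no polygon geometry is handled here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "AreaTable",
    "AdjacencyGraph",
    "SchemaError",
    "ValidationError",
    "load_area_table",
    "compute_expected_counts",
    "compute_shr",
    "standardize",
    "shr_correlation",
    "apportion_population",
    "read_adjacency",
    "write_adjacency_gal",
]


class ValidationError(ValueError):
    """Input data violates an AreaTable or adjacency invariant."""


class SchemaError(ValidationError):
    """A required column is missing from the input file."""


DEFAULT_COLUMNS: dict[str, str] = {
    "area_id": "area_id",
    "population": "population",
    "y1": "y1",
    "y2": "y2",
}


@dataclass
class AreaTable:
    """Per-area populations, observed/expected counts and SHRs.

    ``e1/e2`` and ``shr1/shr2`` are ``None`` ("pending") until
    :func:`compute_expected_counts` / :func:`compute_shr` set them.
    Row order is the canonical area order used by every downstream vector.
    """

    area_id: np.ndarray
    population: np.ndarray
    y1: np.ndarray
    y2: np.ndarray | None = None
    e1: np.ndarray | None = None
    e2: np.ndarray | None = None
    shr1: np.ndarray | None = None
    shr2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.area_id = np.asarray(self.area_id, dtype=object)
        self.population = np.asarray(self.population, dtype=float)
        self.y1 = np.asarray(self.y1)
        if self.y2 is not None:
            self.y2 = np.asarray(self.y2)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.area_id)

    def y(self, disease: int) -> np.ndarray:
        y = self.y1 if disease == 1 else self.y2
        if y is None:
            raise ValidationError(f"disease {disease} counts are not present")
        return y

    def e(self, disease: int) -> np.ndarray:
        e = self.e1 if disease == 1 else self.e2
        if e is None:
            raise ValidationError(
                f"expected counts for disease {disease} are pending; "
                "run compute_expected_counts first"
            )
        return e

    def shr(self, disease: int) -> np.ndarray:
        s = self.shr1 if disease == 1 else self.shr2
        if s is None:
            raise ValidationError(
                f"SHR for disease {disease} is pending; run compute_shr first"
            )
        return s

    def validate(self) -> None:
        ids, counts = np.unique(self.area_id, return_counts=True)
        if (counts > 1).any():
            dup = ids[counts > 1]
            raise ValidationError(f"duplicated area ids: {list(dup)}")
        bad = np.flatnonzero(~(self.population > 0))
        if bad.size:
            raise ValidationError(
                f"non-positive population in rows {bad.tolist()} "
                f"(ids {self.area_id[bad].tolist()})"
            )
        for name, y in (("y1", self.y1), ("y2", self.y2)):
            if y is None:
                continue
            if not np.issubdtype(np.asarray(y).dtype, np.integer):
                if not np.allclose(y, np.round(y)):
                    raise ValidationError(f"{name} contains non-integer counts")
            bad = np.flatnonzero(np.asarray(y) < 0)
            if bad.size:
                raise ValidationError(
                    f"negative {name} count in rows {bad.tolist()} "
                    f"(ids {self.area_id[bad].tolist()})"
                )
        for name, e in (("e1", self.e1), ("e2", self.e2)):
            if e is not None and not (np.asarray(e) > 0).all():
                raise ValidationError(f"{name} must be strictly positive")

    def copy(self) -> "AreaTable":
        return replace(
            self,
            area_id=self.area_id.copy(),
            population=self.population.copy(),
            y1=self.y1.copy(),
            y2=None if self.y2 is None else self.y2.copy(),
            e1=None if self.e1 is None else self.e1.copy(),
            e2=None if self.e2 is None else self.e2.copy(),
            shr1=None if self.shr1 is None else self.shr1.copy(),
            shr2=None if self.shr2 is None else self.shr2.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "area_id": self.area_id,
            "population": self.population,
            "y1": self.y1,
        }
        for name in ("y2", "e1", "e2", "shr1", "shr2"):
            v = getattr(self, name)
            if v is not None:
                cols[name] = v
        return pd.DataFrame(cols)


def load_area_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> AreaTable:
    """Read an area table from a CSV file with a header row.

    ``columns`` maps canonical names (``area_id``, ``population``, ``y1``,
    optionally ``y2``, ``e1``, ``e2``) to the CSV's column names.  Expected
    counts and SHRs are left pending unless ``e1``/``e2`` are mapped.
    """
    mapping = dict(DEFAULT_COLUMNS)
    if columns:
        mapping.update(columns)
    df = pd.read_csv(path)
    required = ["area_id", "population", "y1"]
    for key in required:
        if mapping[key] not in df.columns:
            raise SchemaError(
                f"column '{mapping[key]}' (for {key}) not found in {path}; "
                f"available: {list(df.columns)}"
            )
    kwargs: dict[str, np.ndarray | None] = {
        "area_id": df[mapping["area_id"]].astype(str).to_numpy(dtype=object),
        "population": df[mapping["population"]].to_numpy(dtype=float),
        "y1": df[mapping["y1"]].to_numpy(),
    }
    for key in ("y2", "e1", "e2"):
        col = mapping.get(key)
        if col is not None and col in df.columns:
            kwargs[key] = df[col].to_numpy()
    return AreaTable(**kwargs)  # type: ignore[arg-type]


def compute_expected_counts(table: AreaTable, disease: int) -> AreaTable:
    """Internal standardization: e_i = pop_i * (sum y / sum pop).

    The pooled rate over all areas is applied to each area's population, so
    the expected counts conserve the observed total exactly.
    """
    y = np.asarray(table.y(disease), dtype=float)
    total = y.sum()
    if total <= 0:
        raise ValidationError(
            f"all-zero counts for disease {disease}: pooled rate is degenerate"
        )
    rate = total / table.population.sum()
    e = table.population * rate
    out = table.copy()
    setattr(out, f"e{disease}", e)
    return out


def compute_shr(table: AreaTable, disease: int) -> AreaTable:
    """Standardized hospitalization ratio SHR = Y / E per area."""
    e = np.asarray(table.e(disease), dtype=float)
    if not (e > 0).all():
        raise ValidationError("expected counts must be strictly positive")
    out = table.copy()
    setattr(out, f"shr{disease}", np.asarray(table.y(disease), dtype=float) / e)
    return out


def standardize(table: AreaTable) -> AreaTable:
    """Compute expected counts and SHRs for every disease present."""
    out = table
    for d in (1, 2):
        if (out.y1 if d == 1 else out.y2) is None:
            continue
        if getattr(out, f"e{d}") is None:
            out = compute_expected_counts(out, d)
        out = compute_shr(out, d)
    return out


def shr_correlation(table: AreaTable) -> float:
    """Pearson correlation between the two diseases' SHR vectors."""
    s1, s2 = table.shr(1), table.shr(2)
    if len(s1) < 3:
        raise ValidationError("need at least 3 areas for a correlation")
    if np.ptp(s1) == 0 or np.ptp(s2) == 0:
        raise ValidationError("SHR vector is constant; correlation undefined")
    return float(pearsonr(s1, s2).statistic)


def apportion_population(total: float, weights: Sequence[float]) -> np.ndarray:
    """Split a total population across parts proportionally to weights.

    Used when a census total covers an aggregate of areal units and must be
    allocated to its parts (e.g. by geographic area share).
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValidationError("at least one part required")
    if not (w > 0).all():
        raise ValidationError("weights must be strictly positive")
    if not total > 0:
        raise ValidationError("total must be strictly positive")
    parts = total * w / w.sum()
    # conserve the total exactly despite rounding in the division
    parts[-1] = total - parts[:-1].sum()
    return parts


@dataclass
class AdjacencyGraph:
    """Symmetric neighbour lists over the AreaTable's row order.

    ``neighbours[i]`` is a sorted integer array of i's neighbours;
    ``components`` labels connected components (``n_components`` of them).
    """

    n: int
    neighbours: list[np.ndarray]
    components: np.ndarray = field(init=False)
    n_components: int = field(init=False)
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.neighbours) != self.n:
            raise ValidationError("neighbour list length != n")
        self.neighbours = [
            np.unique(np.asarray(nb, dtype=np.int64)) for nb in self.neighbours
        ]
        for i, nb in enumerate(self.neighbours):
            if ((nb < 0) | (nb >= self.n)).any():
                raise ValidationError(f"neighbour index out of range at node {i}")
            if (nb == i).any():
                raise ValidationError(f"self-loop at node {i}")
            for j in nb:
                if i not in self.neighbours[j]:
                    raise ValidationError(
                        f"asymmetric adjacency: {i}->{j} but not {j}->{i}"
                    )
        self._W = self._build_adjacency()
        self._L: sparse.csr_matrix | None = None
        self.n_components, self.components = connected_components(
            self._W, directed=False
        )
        self._degrees = np.array([len(nb) for nb in self.neighbours], dtype=np.int64)

    @property
    def degrees(self) -> np.ndarray:
        return self._degrees

    def edges(self) -> list[tuple[int, int]]:
        """Unique undirected edges (i < j)."""
        return [(i, int(j)) for i in range(self.n) for j in self.neighbours[i] if i < j]

    def _build_adjacency(self) -> sparse.csr_matrix:
        rows = np.concatenate(
            [np.full(len(nb), i) for i, nb in enumerate(self.neighbours)]
            or [np.empty(0, dtype=np.int64)]
        )
        cols = (
            np.concatenate(self.neighbours)
            if any(len(nb) for nb in self.neighbours)
            else np.empty(0, dtype=np.int64)
        )
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def adjacency_matrix(self) -> sparse.csr_matrix:
        return self._W

    def laplacian(self) -> sparse.csr_matrix:
        if self._L is None:
            D = sparse.diags(self._degrees.astype(float))
            self._L = (D - self._W).tocsr()
        return self._L

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: Sequence[tuple[int, int]],
        ids: Sequence[str] | None = None,
    ) -> "AdjacencyGraph":
        nb: list[list[int]] = [[] for _ in range(n)]
        for i, j in edges:
            if i == j:
                raise ValidationError(f"self-loop at node {i}")
            nb[i].append(j)
            nb[j].append(i)
        return cls(
            n=n,
            neighbours=[np.array(sorted(set(x)), dtype=np.int64) for x in nb],
            ids=None if ids is None else np.asarray(ids, dtype=object),
        )


def _index_of(area_ids: Sequence[str]) -> dict[str, int]:
    return {str(a): i for i, a in enumerate(area_ids)}


def _read_gal(path: Path, area_ids: Sequence[str]) -> AdjacencyGraph:
    idx = _index_of(area_ids)
    tokens_per_line = [
        ln.split() for ln in path.read_text().splitlines() if ln.strip()
    ]
    header = tokens_per_line[0]
    # standard GAL header is either "n" or "0 n <name> <key>"
    n_declared = int(header[0]) if len(header) == 1 else int(header[1])
    if n_declared != len(area_ids):
        raise ValidationError(
            f"GAL declares {n_declared} areas but {len(area_ids)} ids were given"
        )
    neighbours: list[set[int]] = [set() for _ in area_ids]
    pos = 1
    while pos < len(tokens_per_line):
        label, k = tokens_per_line[pos][0], int(tokens_per_line[pos][1])
        if label not in idx:
            raise ValidationError(f"unknown area label in GAL file: {label!r}")
        i = idx[label]
        nbs: list[str] = []
        pos += 1
        while len(nbs) < k:
            nbs.extend(tokens_per_line[pos])
            pos += 1
        for lab in nbs:
            if lab not in idx:
                raise ValidationError(f"unknown neighbour label in GAL file: {lab!r}")
            neighbours[i].add(idx[lab])
    # symmetrize, warning if the file was one-sided
    asym = [
        (i, j)
        for i in range(len(area_ids))
        for j in neighbours[i]
        if i not in neighbours[j]
    ]
    if asym:
        logger.warning("GAL adjacency was asymmetric at %d pairs; symmetrized", len(asym))
        for i, j in asym:
            neighbours[j].add(i)
    edges = [(i, j) for i in range(len(area_ids)) for j in neighbours[i] if i < j]
    return AdjacencyGraph.from_edges(len(area_ids), edges, ids=area_ids)


def _read_edgelist(path: Path, area_ids: Sequence[str]) -> AdjacencyGraph:
    idx = _index_of(area_ids)
    df = pd.read_csv(path, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError("edge list must have two columns")
    rows = df.iloc[:, :2].to_numpy(dtype=object)
    # a header row is one where neither label is a known area id
    if len(rows) and rows[0][0] not in idx and rows[0][1] not in idx:
        rows = rows[1:]
    edges: list[tuple[int, int]] = []
    for a, b in rows:
        if a not in idx or b not in idx:
            raise ValidationError(f"unknown area label in edge list: {a!r}-{b!r}")
        edges.append((idx[a], idx[b]))
    return AdjacencyGraph.from_edges(len(area_ids), edges, ids=area_ids)


def read_adjacency(
    path: str | Path,
    area_ids: Sequence[str],
    format: str | None = None,
) -> AdjacencyGraph:
    """Read adjacency as a GAL spatial-weights file or a 2-column edge list.

    ``format`` is ``"gal"`` or ``"edgelist"``; if omitted it is inferred from
    the file extension (``.gal`` vs anything else).  Every label must appear
    in ``area_ids``, whose order defines node indices.
    """
    p = Path(path)
    fmt = format or ("gal" if p.suffix.lower() == ".gal" else "edgelist")
    if fmt == "gal":
        return _read_gal(p, area_ids)
    if fmt == "edgelist":
        return _read_edgelist(p, area_ids)
    raise ValueError(f"unknown adjacency format: {fmt!r}")


def write_adjacency_gal(
    graph: AdjacencyGraph, path: str | Path, area_ids: Sequence[str] | None = None
) -> None:
    """Write the graph in GAL format (count header, then per-node records)."""
    ids = area_ids if area_ids is not None else graph.ids
    if ids is None:
        ids = [str(i) for i in range(graph.n)]
    lines = [str(graph.n)]
    for i, nb in enumerate(graph.neighbours):
        lines.append(f"{ids[i]} {len(nb)}")
        lines.append(" ".join(str(ids[j]) for j in nb))
    Path(path).write_text("\n".join(lines) + "\n")
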