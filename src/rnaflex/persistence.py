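"""Vietoris–Rips persistent homology of small 3-D point clouds.

The filtration parameter is the Euclidean distance between atoms (Å): a
simplex enters the complex at the largest pairwise distance among its
vertices, and the filtration is truncated at ``max_filtration`` F.  Homology
is computed over Z/2.  Bars still alive at F are reported with death
``+inf``.

Two backends share one contract:

* :func:`rips_persistence` — the production path: union-find for dimension 0
  and a sparse bitset column reduction of the boundary matrix for higher
  dimensions, computed dimension by dimension.
* :func:`brute_force_persistence` — an independent oracle that enumerates
  every simplex, sorts the full boundary matrix globally and reduces it with
  the textbook algorithm.  It is quadratic-ish in the number of simplices and
  restricted to small clouds.

Zero-persistence bars (birth == death) are discarded for dimensions >= 1 —
a loop that is filled the instant it forms carries no information — but kept
for dimension 0 so that the dimension-0 barcode always has exactly one bar
per point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Bar",
    "Barcode",
    "PointCloud",
    "FiltrationConfig",
    "pairwise_distances",
    "rips_persistence",
    "brute_force_persistence",
    "write_barcodes",
    "read_barcodes",
]

#: Number of points above which :func:`brute_force_persistence` refuses to run.
BRUTE_FORCE_MAX_POINTS = 12


class Bar(NamedTuple):
    """A persistence pair ``(birth, death)`` in homology dimension ``dim``.

    ``death`` is ``math.inf`` for classes alive at the end of the filtration.
    Units are Å on both ends.
    """

    birth: float
    death: float
    dim: int


@dataclass(frozen=True)
class PointCloud:
    """A labelled set of 3-D coordinates (Å)."""

    points: np.ndarray
    label: tuple = ()

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise ValueError("point cloud must be a non-empty (n, 3) array")
        if not np.isfinite(pts).all():
            raise ValueError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class Barcode:
    """All bars of one homology dimension for one point selection."""

    bars: tuple
    dim: int
    selection: tuple = ()

    def as_pairs(self) -> list[tuple[float, float]]:
        return [(b.birth, b.death) for b in self.bars]


@dataclass(frozen=True)
class FiltrationConfig:
    """Rips filtration settings: interval [0, F] and top homology dimension.

    The complex is built up to simplex dimension ``max_dim + 1`` so that
    deaths in dimension ``max_dim`` are correct.
    """

    max_filtration: float
    max_dim: int = 1
    #: guard against accidental high-dimensional blow-ups; raise to opt in
    dim_limit: int = 2

    def __post_init__(self) -> None:
        if not (self.max_filtration > 0):
            raise ValueError("max_filtration must be positive")
        if self.max_dim < 0:
            raise ValueError("max_dim must be >= 0")
        if self.max_dim > self.dim_limit:
            raise ValueError(
                f"homology dimension {self.max_dim} exceeds the configured "
                f"limit {self.dim_limit}"
            )


def pairwise_distances(points: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix (Å) of an (n, 3) coordinate array."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("need at least one point")
    if pts.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pts))


# ---------------------------------------------------------------------------
# production backend
# ---------------------------------------------------------------------------


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[max(ri, rj)] = min(ri, rj)
        return True


def _reduce_columns(columns: Iterable[int]):
    """Z/2 column reduction.

    ``columns`` are bitsets over row indices, already in filtration order.
    Yields for each column its reduced pivot row index, or -1 if it reduced
    to zero.  Pivot = highest set bit, i.e. the latest-entering facet.
    """
    pivot_of: dict[int, int] = {}
    out = []
    for col in columns:
        while col:
            piv = col.bit_length() - 1
            other = pivot_of.get(piv)
            if other is None:
                break
            col ^= other
        if col:
            pivot_of[col.bit_length() - 1] = col
            out.append(col.bit_length() - 1)
        else:
            out.append(-1)
    return out


def _neighbour_masks(dist: np.ndarray, F: float) -> list[int]:
    n = dist.shape[0]
    masks = [0] * n
    for i in range(n):
        row = np.flatnonzero(dist[i] <= F)
        m = 0
        for j in row:
            if j != i:
                m |= 1 << int(j)
        masks[i] = m
    return masks


def _bits(mask: int):
    while mask:
        low = mask & -mask
        yield low.bit_length() - 1
        mask ^= low


def rips_persistence(
    cloud: "PointCloud | np.ndarray", cfg: FiltrationConfig
) -> list[Barcode]:
    """Persistence barcodes of the Rips filtration, dims 0..cfg.max_dim."""
    if isinstance(cloud, PointCloud):
        pts, label = cloud.points, cloud.label
    else:
        pts, label = np.asarray(cloud, dtype=float), ()
        pts = PointCloud(pts).points
    n = pts.shape[0]
    F = cfg.max_filtration

    dist = pairwise_distances(pts)

    # --- dimension 0: union-find over edges sorted by (length, lex) -------
    ii, jj = np.triu_indices(n, k=1)
    keep = dist[ii, jj] <= F
    ii, jj, dd = ii[keep], jj[keep], dist[ii, jj][keep]
    order = np.lexsort((jj, ii, dd))
    edges = [(float(dd[k]), int(ii[k]), int(jj[k])) for k in order]

    uf = _UnionFind(n)
    bars0: list[Bar] = []
    positive_edge_idx: list[int] = []  # indices into `edges` of cycle-creating edges
    for e_idx, (d, i, j) in enumerate(edges):
        if uf.union(i, j):
            bars0.append(Bar(0.0, d, 0))
        else:
            positive_edge_idx.append(e_idx)
    n_components = n - len(bars0)
    bars0.extend(Bar(0.0, math.inf, 0) for _ in range(n_components))
    bars0.sort(key=lambda b: (b.birth, b.death))
    result = [Barcode(tuple(bars0), 0, label)]
    if cfg.max_dim == 0:
        return result

    # --- higher dimensions: reduce boundary matrices one dim at a time ----
    masks = _neighbour_masks(dist, F)
    edge_rank = {(i, j): k for k, (_, i, j) in enumerate(edges)}

    # triangles, sorted by (max edge length, lex)
    triangles: list[tuple[float, int, int, int]] = []
    for d, i, j in edges:
        common = masks[i] & masks[j]
        common >>= j + 1  # only k > j, avoids duplicates
        for off in _bits(common):
            k = j + 1 + off
            f = max(d, dist[i, k], dist[j, k])
            if f <= F:
                triangles.append((float(f), i, j, k))
    triangles.sort()

    tri_cols = (
        (1 << edge_rank[(i, j)]) | (1 << edge_rank[(i, k)]) | (1 << edge_rank[(j, k)])
        for _, i, j, k in triangles
    )
    tri_pivots = _reduce_columns(tri_cols)

    paired_edges: dict[int, float] = {}  # edge idx -> death filtration
    positive_tris: list[int] = []
    for t_idx, piv in enumerate(tri_pivots):
        if piv >= 0:
            paired_edges[piv] = triangles[t_idx][0]
        else:
            positive_tris.append(t_idx)

    bars1: list[Bar] = []
    for e_idx in positive_edge_idx:
        birth = edges[e_idx][0]
        death = paired_edges.get(e_idx, math.inf)
        if death > birth:
            bars1.append(Bar(birth, death, 1))
    bars1.sort(key=lambda b: (b.birth, b.death))
    result.append(Barcode(tuple(bars1), 1, label))
    if cfg.max_dim == 1:
        return result

    # dimension 2: reduce the tetrahedron boundary matrix
    tri_rank = {(i, j, k): idx for idx, (_, i, j, k) in enumerate(triangles)}
    tetra: list[tuple[float, int, int, int, int]] = []
    for f, i, j, k in triangles:
        common = (masks[i] & masks[j] & masks[k]) >> (k + 1)
        for off in _bits(common):
            l = k + 1 + off
            g = max(f, dist[i, l], dist[j, l], dist[k, l])
            if g <= F:
                tetra.append((float(g), i, j, k, l))
    tetra.sort()

    tet_cols = (
        (1 << tri_rank[(i, j, k)])
        | (1 << tri_rank[(i, j, l)])
        | (1 << tri_rank[(i, k, l)])
        | (1 << tri_rank[(j, k, l)])
        for _, i, j, k, l in tetra
    )
    tet_pivots = _reduce_columns(tet_cols)
    paired_tris = {
        piv: tetra[t][0] for t, piv in enumerate(tet_pivots) if piv >= 0
    }

    bars2: list[Bar] = []
    for t_idx in positive_tris:
        birth = triangles[t_idx][0]
        death = paired_tris.get(t_idx, math.inf)
        if death > birth:
            bars2.append(Bar(birth, death, 2))
    bars2.sort(key=lambda b: (b.birth, b.death))
    result.append(Barcode(tuple(bars2), 2, label))
    return result


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_persistence(
    cloud: "PointCloud | np.ndarray", cfg: FiltrationConfig
) -> list[Barcode]:
    """Full-matrix persistence by global simplex enumeration and reduction.

    Enumerates every simplex up to dimension ``cfg.max_dim + 1`` whose
    diameter is <= F, sorts them by (filtration, dimension, vertex tuple),
    and reduces the complete Z/2 boundary matrix.  Intended as an
    independent correctness oracle for :func:`rips_persistence`; refuses
    clouds larger than ``BRUTE_FORCE_MAX_POINTS``.
    """
    from itertools import combinations

    if isinstance(cloud, PointCloud):
        pts, label = cloud.points, cloud.label
    else:
        pts, label = PointCloud(np.asarray(cloud, dtype=float)).points, ()
    n = pts.shape[0]
    if n > BRUTE_FORCE_MAX_POINTS:
        raise ValueError(
            f"brute-force oracle limited to {BRUTE_FORCE_MAX_POINTS} points, got {n}"
        )
    F = cfg.max_filtration
    dist = pairwise_distances(pts)

    simplices: list[tuple[float, int, tuple[int, ...]]] = []
    for d in range(cfg.max_dim + 2):
        for verts in combinations(range(n), d + 1):
            if d == 0:
                f = 0.0
            else:
                f = max(dist[a, b] for a, b in combinations(verts, 2))
            if f <= F:
                simplices.append((float(f), d, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))

    index_of = {verts: idx for idx, (_, _, verts) in enumerate(simplices)}
    columns = []
    for f, d, verts in simplices:
        col = 0
        if d > 0:
            for face in combinations(verts, d):
                col |= 1 << index_of[face]
        columns.append(col)

    pivots = _reduce_columns(columns)
    died_at: dict[int, float] = {}
    for col_idx, piv in enumerate(pivots):
        if piv >= 0:
            died_at[piv] = simplices[col_idx][0]

    # a simplex is a birth iff its own column reduced to zero
    bars: dict[int, list[Bar]] = {d: [] for d in range(cfg.max_dim + 1)}
    for idx, ((f, d, _), piv) in enumerate(zip(simplices, pivots)):
        if piv != -1 or d > cfg.max_dim:
            continue
        death = died_at.get(idx, math.inf)
        if death > f or d == 0:
            bars[d].append(Bar(f, death, d))
    return [
        Barcode(tuple(sorted(bars[d], key=lambda b: (b.birth, b.death))), d, label)
        for d in range(cfg.max_dim + 1)
    ]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_barcodes(records: Sequence[tuple[tuple, Barcode]], path) -> None:
    """Write (sample_id, barcode) records to a CSV with an ``+inf`` token."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "element", "dim", "birth", "death"])
        for sample_id, bc in records:
            element = bc.selection[-1] if bc.selection else ""
            for bar in bc.bars:
                death = "+inf" if math.isinf(bar.death) else repr(bar.death)
                w.writerow(["/".join(map(str, sample_id)), element, bc.dim, repr(bar.birth), death])


def read_barcodes(path) -> list[tuple[str, Barcode]]:
    """Inverse of :func:`write_barcodes`; groups rows back into barcodes."""
    import csv

    grouped: dict[tuple[str, str, int], list[Bar]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["sample_id"], row["element"], int(row["dim"]))
            death = math.inf if row["death"] == "+inf" else float(row["death"])
            grouped.setdefault(key, []).append(Bar(float(row["birth"]), death, int(row["dim"])))
    return [
        (sid, Barcode(tuple(bars), dim, (element,) if element else ()))
        for (sid, element, dim), bars in grouped.items()
    ]
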