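"""Vietoris–Rips filtrations and persistent homology over GF(2).

The VR complex at scale δ contains a simplex for every set of points whose
pairwise distances are all ≤ δ (the appearance value of a simplex is the
maximum of its edge lengths). Sweeping δ from 0 upward yields a filtration;
persistent homology records, per degree, the (birth, death) scales of every
topological feature: connected components (degree 0), loops (degree 1) and
enclosed voids (degree 2).

Persistence pairs are computed by the standard boundary-matrix reduction over
GF(2), with columns stored as Python integers (bitsets) so column additions
are single XORs. `brute_force_betti` is an independent oracle: it assembles
boundary operators of the complex frozen at one scale and takes their GF(2)
ranks directly — a different codepath used to cross-check the reduction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .cloud_io import DistanceMatrix

__all__ = [
    "FilteredSimplex",
    "Filtration",
    "PersistencePair",
    "PersistenceDiagram",
    "build_vr_filtration",
    "compute_persistence",
    "vr_diagram",
    "betti_at",
    "brute_force_betti",
    "write_diagram_csv",
    "read_diagram_csv",
]


class FilteredSimplex(NamedTuple):
    """A simplex (1–4 vertices) with the filtration scale at which it appears."""

    vertices: tuple[int, ...]
    value: float

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1


@dataclass(frozen=True)
class Filtration:
    """VR simplices sorted by (value, dimension, lexicographic vertices).

    The sort key guarantees every face precedes its cofaces: a face has a
    value ≤ its coface's and strictly smaller dimension at equal value.
    """

    simplices: tuple[FilteredSimplex, ...]
    delta_max: float
    n_points: int
    max_dim: int | None = None  # configured cap; inferred when omitted

    def __post_init__(self) -> None:
        if self.max_dim is None:
            inferred = max((s.dim for s in self.simplices), default=0)
            object.__setattr__(self, "max_dim", inferred)

    def __len__(self) -> int:
        return len(self.simplices)


class PersistencePair(NamedTuple):
    degree: int
    birth: float
    death: float  # math.inf for essential classes

    @property
    def persistence(self) -> float:
        return self.death - self.birth

    @property
    def is_trivial(self) -> bool:
        """Zero-persistence pair (born and dying at the same scale)."""
        return self.death == self.birth


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (degree, birth, death) persistence pairs for one cloud."""

    pairs: tuple[PersistencePair, ...]
    n_points: int
    delta_max: float

    def of_degree(
        self, degree: int, drop_trivial: bool = False
    ) -> tuple[PersistencePair, ...]:
        return tuple(
            p
            for p in self.pairs
            if p.degree == degree and not (drop_trivial and p.is_trivial)
        )


def build_vr_filtration(
    d: DistanceMatrix, delta_max: float, max_dim: int = 2
) -> Filtration:
    """Build the VR filtration capped at scale ``delta_max``.

    Contains every vertex, every edge of length ≤ ``delta_max``, and every
    triangle/tetrahedron all of whose edges are present; a simplex's value is
    its longest edge. ``max_dim`` ≤ 3: degree-2 homology needs nothing beyond
    dimension-3 simplices.
    """
    if delta_max <= 0:
        raise ValueError("delta_max must be positive")
    if not 1 <= max_dim <= 3:
        raise ValueError("max_dim must be between 1 and 3")
    dm = d.d
    n = d.n
    simplices: list[FilteredSimplex] = [FilteredSimplex((i,), 0.0) for i in range(n)]
    adj = (dm <= delta_max) & ~np.eye(n, dtype=bool)
    edge_idx = np.argwhere(np.triu(adj))
    for i, j in edge_idx:
        simplices.append(FilteredSimplex((int(i), int(j)), float(dm[i, j])))
    if max_dim >= 2:
        for i, j in edge_idx:
            common = np.nonzero(adj[i] & adj[j])[0]
            for k in common[common > j]:
                verts3 = (int(i), int(j), int(k))
                val3 = float(max(dm[i, j], dm[i, k], dm[j, k]))
                simplices.append(FilteredSimplex(verts3, val3))
                if max_dim >= 3:
                    common3 = np.nonzero(adj[i] & adj[j] & adj[k])[0]
                    for l in common3[common3 > k]:
                        val4 = float(max(val3, dm[i, l], dm[j, l], dm[k, l]))
                        simplices.append(
                            FilteredSimplex((*verts3, int(l)), val4)
                        )
    simplices.sort(key=lambda s: (s.value, s.dim, s.vertices))
    return Filtration(tuple(simplices), float(delta_max), n, max_dim)


def compute_persistence(f: Filtration, max_degree: int = 1) -> PersistenceDiagram:
    """Persistence pairs of a filtration by GF(2) boundary-matrix reduction.

    Each column is the boundary of one simplex in filtration order, stored as
    an integer bitset. Left-to-right reduction pairs a killing simplex with the
    creator holding its pivot row; unpaired creators are essential (death ∞).
    Zero-persistence pairs are retained (flagged via ``is_trivial``).
    """
    if max_degree > f.max_dim - 1:
        raise ValueError(
            f"max_degree={max_degree} needs simplices of dimension "
            f"{max_degree + 1}; filtration was capped at dimension {f.max_dim}"
        )
    index: dict[tuple[int, ...], int] = {
        s.vertices: j for j, s in enumerate(f.simplices)
    }
    columns: dict[int, int] = {}  # reduced non-zero columns by column index
    pivot_of_row: dict[int, int] = {}
    paired: set[int] = set()
    pairs: list[PersistencePair] = []
    for j, s in enumerate(f.simplices):
        if s.dim == 0:
            continue
        col = 0
        for face in combinations(s.vertices, s.dim):
            try:
                col ^= 1 << index[face]
            except KeyError:
                raise ValueError(
                    f"filtration is not closed under faces: {face} missing"
                ) from None
        while col:
            low = col.bit_length() - 1
            other = pivot_of_row.get(low)
            if other is None:
                break
            col ^= columns[other]
        if col:
            low = col.bit_length() - 1
            pivot_of_row[low] = j
            columns[j] = col
            paired.add(low)
            paired.add(j)
            creator = f.simplices[low]
            if creator.dim <= max_degree:
                pairs.append(
                    PersistencePair(creator.dim, creator.value, s.value)
                )
    for j, s in enumerate(f.simplices):
        if j not in paired and s.dim <= max_degree:
            pairs.append(PersistencePair(s.dim, s.value, math.inf))
    pairs.sort()
    return PersistenceDiagram(tuple(pairs), f.n_points, f.delta_max)


def vr_diagram(
    d: DistanceMatrix, delta_max: float, max_degree: int = 1
) -> PersistenceDiagram:
    """Convenience wrapper: filtration + reduction in one call."""
    f = build_vr_filtration(d, delta_max, max_dim=max_degree + 1)
    return compute_persistence(f, max_degree=max_degree)


def betti_at(
    diagram: PersistenceDiagram, delta: float, max_degree: int | None = None
) -> dict[int, int]:
    """Betti numbers at scale δ: features with birth ≤ δ < death, per degree.

    Reports degrees 0..``max_degree``; by default up to the highest degree
    appearing in the diagram (at least 2, so void counts are always present).
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if max_degree is None:
        max_degree = max((p.degree for p in diagram.pairs), default=0)
        max_degree = max(max_degree, 2)
    counts = {deg: 0 for deg in range(max_degree + 1)}
    for p in diagram.pairs:
        if p.degree <= max_degree and p.birth <= delta < p.death:
            counts[p.degree] += 1
    return counts


def _gf2_rank(mat: np.ndarray) -> int:
    """Rank of a 0/1 matrix over GF(2) by Gaussian elimination on bitset rows."""
    rows = [int("".join(str(int(b)) for b in row[::-1]), 2) for row in mat] if mat.size else []
    rank = 0
    for col in range(mat.shape[1] if mat.size else 0):
        bit = 1 << col
        pivot = next((i for i, r in enumerate(rows) if r & bit), None)
        if pivot is None:
            continue
        pivot_row = rows.pop(pivot)
        rows = [r ^ pivot_row if r & bit else r for r in rows]
        rank += 1
    return rank


def brute_force_betti(
    d: DistanceMatrix, delta: float, max_degree: int = 2, n_limit: int = 10
) -> dict[int, int]:
    """Betti numbers of the VR complex frozen at scale δ, computed from scratch.

    Enumerates all simplices up to dimension ``max_degree + 1`` whose edges are
    all ≤ δ, assembles each boundary operator as an explicit 0/1 matrix, and
    uses β_k = #C_k − rank ∂_k − rank ∂_{k+1} over GF(2). Combinatorial cost:
    refuses clouds above ``n_limit`` points.
    """
    n = d.n
    if n > n_limit:
        raise ValueError(f"brute_force_betti limited to {n_limit} points, got {n}")
    dm = d.d
    simplices: dict[int, list[tuple[int, ...]]] = {}
    for k in range(max_degree + 2):
        simplices[k] = [
            verts
            for verts in combinations(range(n), k + 1)
            if all(dm[a, b] <= delta for a, b in combinations(verts, 2))
        ]
    betti: dict[int, int] = {}
    for k in range(max_degree + 1):
        c_k = simplices[k]
        idx = {verts: i for i, verts in enumerate(c_k)}
        # rank of ∂_k : C_k -> C_{k-1}
        if k == 0 or not c_k:
            rank_k = 0
        else:
            lower = {verts: i for i, verts in enumerate(simplices[k - 1])}
            mat = np.zeros((len(lower), len(c_k)), dtype=np.uint8)
            for j, verts in enumerate(c_k):
                for face in combinations(verts, k):
                    mat[lower[face], j] = 1
            rank_k = _gf2_rank(mat)
        # rank of ∂_{k+1} : C_{k+1} -> C_k
        upper = simplices[k + 1]
        if not upper or not c_k:
            rank_k1 = 0
        else:
            mat = np.zeros((len(c_k), len(upper)), dtype=np.uint8)
            for j, verts in enumerate(upper):
                for face in combinations(verts, k + 1):
                    mat[idx[face], j] = 1
            rank_k1 = _gf2_rank(mat)
        betti[k] = len(c_k) - rank_k - rank_k1
    return betti


def dominant_features(
    diagram: PersistenceDiagram, degree: int, ratio: float = 0.5
) -> tuple[PersistencePair, ...]:
    """Features of one degree whose persistence is ≥ ``ratio`` × the maximum.

    Deaths beyond the filtration cap (reported ∞) are truncated to
    ``delta_max`` for the comparison, so essential classes participate.
    Separates signal features (e.g. the two independent loops of a torus)
    from sampling noise when the persistence gap is clear.
    """
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    pairs = diagram.of_degree(degree)
    if not pairs:
        return ()
    cap = diagram.delta_max

    def pers(p: PersistencePair) -> float:
        return min(p.death, cap) - p.birth

    top = max(pers(p) for p in pairs)
    return tuple(
        sorted((p for p in pairs if pers(p) >= ratio * top), key=pers, reverse=True)
    )


def write_diagram_csv(diagram: PersistenceDiagram, path: str | Path) -> None:
    """Serialise as ``degree,birth,death`` CSV; essential deaths written ``inf``."""
    lines = ["degree,birth,death"]
    for p in diagram.pairs:
        death = "inf" if math.isinf(p.death) else format(p.death, ".17g")
        lines.append(f"{p.degree},{format(p.birth, '.17g')},{death}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_diagram_csv(
    path: str | Path, n_points: int = 0, delta_max: float = math.inf
) -> PersistenceDiagram:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "degree,birth,death":
        raise ValueError(f"{path}: expected 'degree,birth,death' header")
    pairs = []
    for line in lines[1:]:
        if not line.strip():
            continue
        deg, birth, death = line.split(",")
        pairs.append(PersistencePair(int(deg), float(birth), float(death)))
    if n_points == 0:
        n_points = sum(1 for p in pairs if p.degree == 0)
    return PersistenceDiagram(tuple(sorted(pairs)), n_points, delta_max)
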