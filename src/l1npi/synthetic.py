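"""Synthetic point-cloud generators: exact fixtures and water-like ensembles.

Exact geometric fixtures (hexagon, square, point pair) have closed-form
persistence and anchor the test surface. Sampled manifolds (noisy circle,
torus) exercise the detection of loops and voids. The perturbed-lattice
generator stands in for molecular-dynamics oxygen clouds: lattice sites
(diamond, mimicking the tetrahedral oxygen network of water, or simple cubic)
are jittered by isotropic Gaussian noise and randomly subsampled. Jitter
width plays the role of the structural differences between interaction
potentials — it directly controls the width of the nearest- and
next-nearest-neighbour distance distributions the descriptor reads — while
the subsample fraction varies system size at fixed density.

All generators are deterministic per seed, and ensemble frame i does not
depend on how many frames are requested (per-frame seeds are derived from
the master seed with a counter-based stream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cloud_io import PointCloud

__all__ = [
    "GeneratorSpec",
    "make_hexagon",
    "make_square",
    "make_pair",
    "make_noisy_circle",
    "make_torus_sample",
    "make_lattice_box",
    "generate_ensemble",
]


def make_hexagon(d: float = 1.0) -> PointCloud:
    """Six coplanar vertices of a regular hexagon, nearest-neighbour distance d.

    The circumradius of a regular hexagon equals its side, so vertices sit at
    radius d; centroid at the origin. Pairwise distances are d (adjacent),
    √3·d (next-nearest) and 2d (opposite).
    """
    if d <= 0:
        raise ValueError("spacing d must be positive")
    angles = np.arange(6) * np.pi / 3
    coords = d * np.c_[np.cos(angles), np.sin(angles), np.zeros(6)]
    return PointCloud(coords, elements=("O",) * 6, label="hexagon")


def make_square(side: float = 1.0) -> PointCloud:
    """Unit-square fixture; its single loop is born at ``side``, dies at √2·side."""
    if side <= 0:
        raise ValueError("side must be positive")
    base = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    coords = side * (base - base.mean(axis=0))
    return PointCloud(coords, elements=("O",) * 4, label="square")


def make_pair(r: float = 1.0) -> PointCloud:
    """Two points at distance r: the minimal merging example."""
    if r <= 0:
        raise ValueError("r must be positive")
    coords = np.array([[-r / 2, 0, 0], [r / 2, 0, 0]])
    return PointCloud(coords, elements=("O",) * 2, label="pair")


def make_noisy_circle(
    n: int, radius: float = 1.0, noise_sd: float = 0.0, seed: int = 0
) -> PointCloud:
    """n points at uniform angles on a circle with Gaussian radial noise, z = 0."""
    if n < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2 * np.pi, n)
    r = radius + rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.full(n, radius)
    coords = np.c_[r * np.cos(theta), r * np.sin(theta), np.zeros(n)]
    return PointCloud(coords, label="noisy_circle")


def make_torus_sample(
    R: float, r: float, n: int, seed: int = 0
) -> PointCloud:
    """Area-uniform sample of the torus (major radius R, minor radius r).

    Uniform sampling in the angles oversamples the inner rim; the minor angle
    is rejection-sampled against the Jacobian (R + r·cosθ)/(R + r) to correct
    for surface area.
    """
    if not R > r > 0:
        raise ValueError("need R > r > 0 (torus must not self-intersect)")
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    theta = np.empty(n)
    filled = 0
    while filled < n:
        cand = rng.uniform(0.0, 2 * np.pi, 2 * (n - filled))
        accept = rng.uniform(0.0, 1.0, cand.size) < (R + r * np.cos(cand)) / (R + r)
        keep = cand[accept][: n - filled]
        theta[filled : filled + keep.size] = keep
        filled += keep.size
    x = (R + r * np.cos(theta)) * np.cos(phi)
    y = (R + r * np.cos(theta)) * np.sin(phi)
    z = r * np.sin(theta)
    return PointCloud(np.c_[x, y, z], label="torus")


_DIAMOND_BASIS = (
    np.array(
        [
            [0, 0, 0], [0, 2, 2], [2, 0, 2], [2, 2, 0],
            [1, 1, 1], [1, 3, 3], [3, 1, 3], [3, 3, 1],
        ],
        dtype=float,
    )
    / 4.0
)


def make_lattice_box(
    lattice: str,
    cells_per_side: int,
    spacing: float,
    jitter_sd: float = 0.0,
    subsample_fraction: float = 1.0,
    seed: int = 0,
    subsample_mode: str = "random",
) -> PointCloud:
    """Jittered, subsampled lattice in a cubic box (recorded for optional PBC).

    ``lattice`` is ``"diamond"`` (8 sites per conventional cell of edge
    ``spacing``; nearest-neighbour distance spacing·√3/4, the tetrahedral
    geometry of the water oxygen network) or ``"cubic"`` (1 site per cell,
    nearest-neighbour distance = spacing). Sites are displaced by isotropic
    Gaussian noise of width ``jitter_sd``; ``subsample_fraction`` keeps that
    fraction of sites.

    ``subsample_mode`` controls what "removing molecules" means:

    * ``"random"`` — sites deleted uniformly at random. This dilutes the
      lattice, so it lowers the density and introduces vacancies: the
      remaining *structure* changes with the fraction.
    * ``"block"`` — the leading fraction of sites in lexicographic position
      order is kept: a contiguous sub-volume at unchanged density and local
      structure, i.e. a genuinely smaller system of the same material. Size
      classes for size-independence studies use this mode.
    """
    if cells_per_side < 2:
        raise ValueError("cells_per_side must be >= 2")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must be in (0, 1]")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if subsample_mode not in ("random", "block"):
        raise ValueError(f"unknown subsample_mode {subsample_mode!r}")
    if lattice == "diamond":
        basis = _DIAMOND_BASIS
    elif lattice == "cubic":
        basis = np.zeros((1, 3))
    else:
        raise ValueError(f"unknown lattice {lattice!r}")
    cells = np.arange(cells_per_side)
    offsets = np.array(np.meshgrid(cells, cells, cells, indexing="ij")).reshape(3, -1).T
    sites = (offsets[:, None, :] + basis[None, :, :]).reshape(-1, 3) * spacing
    rng = np.random.default_rng(seed)
    n_keep = int(round(subsample_fraction * len(sites)))
    if n_keep < 4:
        raise ValueError("parameters yield fewer than 4 points")
    if subsample_mode == "random":
        keep = rng.choice(len(sites), size=n_keep, replace=False)
        keep.sort()
        coords = sites[keep]
    else:
        order = np.lexsort((sites[:, 2], sites[:, 1], sites[:, 0]))
        coords = sites[order][:n_keep]
    if jitter_sd > 0:
        coords = coords + rng.normal(0.0, jitter_sd, coords.shape)
    box = np.full(3, cells_per_side * spacing)
    return PointCloud(
        coords, elements=("O",) * n_keep, box=box, label=f"{lattice}_lattice"
    )


@dataclass(frozen=True)
class GeneratorSpec:
    """Fully-seeded recipe for an ensemble of frames.

    ``kind`` selects the generator; ``parameters`` are passed through to it.
    Identical spec + seed gives bit-identical frames, and frame i is the same
    whatever ``n_frames`` is (per-frame seeds are ``seed + 1000003 * i`` mod
    2^31, a fixed counter stream).
    """

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0
    n_frames: int = 1
    label: str = ""

    _STOCHASTIC = {"noisy_circle", "torus", "lattice_box"}
    _KINDS = {"hexagon", "square", "pair", "noisy_circle", "torus", "lattice_box"}

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    def frame_seed(self, i: int) -> int:
        return (self.seed + 1000003 * i) % (2**31)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "parameters": self.parameters,
                "seed": self.seed,
                "n_frames": self.n_frames,
                "label": self.label,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneratorSpec":
        d = json.loads(text)
        return cls(
            kind=d["kind"],
            parameters=dict(d.get("parameters", {})),
            seed=int(d.get("seed", 0)),
            n_frames=int(d.get("n_frames", 1)),
            label=d.get("label", ""),
        )


_MAKERS = {
    "hexagon": make_hexagon,
    "square": make_square,
    "pair": make_pair,
    "noisy_circle": make_noisy_circle,
    "torus": make_torus_sample,
    "lattice_box": make_lattice_box,
}


def generate_ensemble(spec: GeneratorSpec) -> list[PointCloud]:
    """Generate ``spec.n_frames`` independent frames of the requested kind."""
    maker = _MAKERS[spec.kind]
    clouds: list[PointCloud] = []
    for i in range(spec.n_frames):
        kwargs = dict(spec.parameters)
        if spec.kind in GeneratorSpec._STOCHASTIC:
            kwargs["seed"] = spec.frame_seed(i)
        cloud = maker(**kwargs)
        clouds.append(
            PointCloud(
                cloud.coords,
                elements=cloud.elements,
                box=cloud.box,
                frame_index=i,
                label=spec.label or cloud.label,
            )
        )
    return clouds
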