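"""Persistence images: rasterising a persistence diagram onto a pixel grid.

A diagram point (birth b, death d) is mapped to birth–persistence coordinates
(b, p = d − b), smoothed with an isotropic Gaussian g and multiplied by a
weighting φ that vanishes on the diagonal (φ(x, 0) = 0, for stability: points
of zero persistence carry no signal). The weighted surface is integrated over
a fixed grid of pixels — by default 50 × 50 — giving a fixed-size grayscale
image that can be averaged pixelwise across trajectory frames.

Two Gaussian conventions are exposed. The default, ``kernel="2pi"``, uses
2πσ² in the exponent denominator::

    g(x, y) = 1/(2πσ²) · exp(−((x−b)² + (y−p)²) / (2πσ²))

``kernel="canonical"`` uses the usual bivariate normal denominator 2σ². The
two differ only by an effective rescaling of σ (by √π); the convention is
recorded in the grid metadata and images are only comparable at matching
settings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .vr import PersistenceDiagram

__all__ = [
    "ImageGrid",
    "PersistenceImage",
    "to_birth_persistence",
    "gaussian_surface",
    "weight",
    "render_image",
    "diagram_to_image",
    "auto_grid",
    "write_image_csv",
    "read_image_csv",
    "save_image_png",
]

KERNELS = ("2pi", "canonical")


@dataclass(frozen=True)
class ImageGrid:
    """Pixel grid over (birth, persistence) space, in Å.

    ``sigma`` defaults to 0.1 × the persistence extent; the grid must be fixed
    per experiment so pixels are comparable across frames and systems.
    """

    birth_range: tuple[float, float]
    pers_range: tuple[float, float]
    nx: int = 50
    ny: int = 50
    sigma: float | None = None
    kernel: str = "2pi"

    def __post_init__(self) -> None:
        b_lo, b_hi = self.birth_range
        p_lo, p_hi = self.pers_range
        if not (b_hi > b_lo >= 0 and p_hi > p_lo >= 0):
            raise ValueError("ranges must satisfy hi > lo >= 0")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx, ny must be >= 1")
        if self.sigma is None:
            object.__setattr__(self, "sigma", 0.1 * p_hi)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")
        object.__setattr__(self, "birth_range", (float(b_lo), float(b_hi)))
        object.__setattr__(self, "pers_range", (float(p_lo), float(p_hi)))

    @property
    def x_centers(self) -> np.ndarray:
        b_lo, b_hi = self.birth_range
        edges = np.linspace(b_lo, b_hi, self.nx + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        p_lo, p_hi = self.pers_range
        edges = np.linspace(p_lo, p_hi, self.ny + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def pixel_area(self) -> float:
        b_lo, b_hi = self.birth_range
        p_lo, p_hi = self.pers_range
        return (b_hi - b_lo) / self.nx * (p_hi - p_lo) / self.ny

    def to_dict(self) -> dict:
        return {
            "birth_range": list(self.birth_range),
            "pers_range": list(self.pers_range),
            "nx": self.nx,
            "ny": self.ny,
            "sigma": self.sigma,
            "kernel": self.kernel,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImageGrid":
        return cls(
            tuple(d["birth_range"]),
            tuple(d["pers_range"]),
            d["nx"],
            d["ny"],
            d["sigma"],
            d.get("kernel", "2pi"),
        )


@dataclass(frozen=True)
class PersistenceImage:
    """ny × nx non-negative intensity matrix over an :class:`ImageGrid`.

    ``pixels[i, j]`` covers the i-th persistence row and j-th birth column
    (row 0 at the lowest persistence).
    """

    grid: ImageGrid
    pixels: np.ndarray
    degree: int
    n_features: int

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.shape != (self.grid.ny, self.grid.nx):
            raise ValueError(
                f"pixels shape {pixels.shape} != grid (ny={self.grid.ny}, nx={self.grid.nx})"
            )
        if np.any(pixels < 0):
            raise ValueError("persistence image pixels must be non-negative")
        object.__setattr__(self, "pixels", pixels)

    @property
    def total_mass(self) -> float:
        return float(self.pixels.sum())


def to_birth_persistence(
    diagram: PersistenceDiagram, degree: int
) -> list[tuple[float, float]]:
    """Finite pairs of one degree in (birth, persistence) coordinates.

    Essential classes (death = ∞) are excluded: they have no finite
    persistence to rasterise.
    """
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1 or 2")
    return [
        (p.birth, p.death - p.birth)
        for p in diagram.of_degree(degree)
        if math.isfinite(p.death)
    ]


def _exponent_denominator(grid: ImageGrid) -> float:
    s2 = grid.sigma**2
    return 2.0 * math.pi * s2 if grid.kernel == "2pi" else 2.0 * s2


def gaussian_surface(
    point: tuple[float, float], grid: ImageGrid
) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """The Gaussian bump centred at one diagram point, as a callable g(x, y).

    Peak value is 1/(2πσ²) at the centre under either kernel convention.
    """
    b, p = point
    denom = _exponent_denominator(grid)
    amp = 1.0 / (2.0 * math.pi * grid.sigma**2)

    def g(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return amp * np.exp(-((x - b) ** 2 + (y - p) ** 2) / denom)

    return g


def weight(x: np.ndarray, y: np.ndarray, grid: ImageGrid) -> np.ndarray:
    """Diagonal-vanishing weighting φ: linear ramp in persistence.

    φ(x, y) = clip(y / p_hi, 0, 1) — zero on the diagonal (y = 0),
    non-decreasing in y, saturating at 1 for y ≥ the grid's persistence
    ceiling; independent of birth.
    """
    _ = x  # φ does not depend on birth; argument kept for the (x, y) contract
    p_hi = grid.pers_range[1]
    return np.clip(np.asarray(y, dtype=float) / p_hi, 0.0, 1.0)


def render_image(
    points: Sequence[tuple[float, float]],
    grid: ImageGrid,
    degree: int = 1,
    weight_fn: Callable[[np.ndarray, np.ndarray, ImageGrid], np.ndarray] | None = weight,
) -> PersistenceImage:
    """Integrate Σ g·φ over the pixels (midpoint rule: centre value × area).

    Additive in the diagram: the image of a union of point lists is the
    pixelwise sum of the individual images. Points outside the grid still
    contribute their Gaussian tails. ``weight_fn=None`` disables φ (useful for
    calibration checks).
    """
    xs = grid.x_centers
    ys = grid.y_centers
    pixels = np.zeros((grid.ny, grid.nx))
    denom = _exponent_denominator(grid)
    amp = 1.0 / (2.0 * math.pi * grid.sigma**2)
    for b, p in points:
        fx = np.exp(-((xs - b) ** 2) / denom)
        fy = np.exp(-((ys - p) ** 2) / denom)
        pixels += amp * np.outer(fy, fx)
    if weight_fn is not None:
        xg, yg = np.meshgrid(xs, ys)
        pixels *= weight_fn(xg, yg, grid)
    pixels *= grid.pixel_area
    return PersistenceImage(grid, pixels, degree=degree, n_features=len(points))


def diagram_to_image(
    diagram: PersistenceDiagram, degree: int, grid: ImageGrid
) -> PersistenceImage:
    """Full pipeline step: diagram → (b, p) points of one degree → image."""
    return render_image(to_birth_persistence(diagram, degree), grid, degree=degree)


def auto_grid(
    diagrams: Iterable[PersistenceDiagram],
    degree: int,
    nx: int = 50,
    ny: int = 50,
    pad: float = 0.05,
    sigma: float | None = None,
    kernel: str = "2pi",
) -> ImageGrid:
    """Scan diagrams and build a shared grid padded by ``pad`` (fraction).

    Convenience for choosing one fixed grid per experiment; the result must
    then be reused for every frame of that experiment.
    """
    births: list[float] = []
    pers: list[float] = []
    for dg in diagrams:
        for b, p in to_birth_persistence(dg, degree):
            if p > 0:  # zero-persistence pairs carry no image mass
                births.append(b)
                pers.append(p)
    if not births:
        raise ValueError("no finite diagram points to scan")
    b_hi = max(births) * (1 + pad)
    p_hi = max(pers) * (1 + pad)
    if p_hi <= 0:
        raise ValueError("all scanned points have zero persistence")
    return ImageGrid((0.0, max(b_hi, 1e-12)), (0.0, p_hi), nx, ny, sigma, kernel)


def write_image_csv(image: PersistenceImage, path: str | Path) -> None:
    """CSV matrix plus a JSON sidecar (same stem, ``.json``) with the metadata."""
    path = Path(path)
    np.savetxt(path, image.pixels, delimiter=",", fmt="%.17g")
    meta = {
        "grid": image.grid.to_dict(),
        "degree": image.degree,
        "n_features": image.n_features,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_image_csv(path: str | Path) -> PersistenceImage:
    path = Path(path)
    pixels = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(".json").read_text())
    return PersistenceImage(
        ImageGrid.from_dict(meta["grid"]),
        pixels,
        degree=meta["degree"],
        n_features=meta["n_features"],
    )


def save_image_png(image_pixels: np.ndarray, path: str | Path, title: str = "") -> None:
    """Intensity-scaled PNG for visual inspection only (never parsed back)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(np.asarray(image_pixels), origin="lower", cmap="viridis")
    fig.colorbar(im, ax=ax)
    if title:
        ax.set_title(title)
    ax.set_xlabel("birth")
    ax.set_ylabel("persistence")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
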