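"""L1-normalised persistence images (L1NPIs) and flat descriptor vectors.

The number of persistent features — and hence the total mass of a persistence
image — scales with the number of points in the system. Dividing an image by
its total pixel mass,

    L1NPI[i, j] = I[i, j] / Σ_{i,j} I[i, j],

yields a descriptor whose integral is 1 regardless of system size, so systems
with vastly different molecule counts can be compared. Averaging is done per
frame *then* across frames (the mean of L1NPIs): this is not the same object
as the L1-normalised mean image whenever raw frame totals differ, and the
per-frame normalisation is the one that defines the descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .image import ImageGrid, PersistenceImage

__all__ = [
    "L1NPI",
    "DescriptorVector",
    "normalize",
    "mean_l1npi",
    "mean_image",
    "flatten",
    "unflatten",
    "descriptor_frame",
]

_SUM_TOL = 1e-9


class EmptyImageError(ValueError):
    """Raised when normalising an all-zero image (e.g. an empty diagram)."""


class GridMismatchError(ValueError):
    """Raised when images on incompatible grids are combined."""


@dataclass(frozen=True)
class L1NPI:
    """A persistence image normalised to unit total pixel mass."""

    grid: ImageGrid
    pixels: np.ndarray
    degree: int
    source_frames: int = 1

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("pixel shape does not match grid")
        if np.any(pixels < 0):
            raise ValueError("L1NPI pixels must be non-negative")
        total = pixels.sum()
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"L1NPI must sum to 1 (got {total!r})")
        object.__setattr__(self, "pixels", pixels)


@dataclass(frozen=True)
class DescriptorVector:
    """Row-major flattening of an L1NPI (length nx·ny; 2500 at defaults)."""

    values: np.ndarray
    label: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())


def _check_grids(images: Sequence[L1NPI | PersistenceImage]) -> None:
    ref = images[0]
    for im in images[1:]:
        diffs = [
            name
            for name in ("birth_range", "pers_range", "nx", "ny", "sigma", "kernel")
            if getattr(im.grid, name) != getattr(ref.grid, name)
        ]
        if im.degree != ref.degree:
            diffs.append("degree")
        if diffs:
            raise GridMismatchError(
                f"incompatible images; differing fields: {', '.join(diffs)}"
            )


def normalize(image: PersistenceImage) -> L1NPI:
    """Divide by the total pixel mass so the image sums to 1.

    Scale-invariant (c·I and I normalise identically) and idempotent. An
    all-zero image — an empty diagram in this degree — raises
    :class:`EmptyImageError` rather than propagating NaNs.
    """
    total = image.total_mass
    if total <= 0:
        raise EmptyImageError(
            f"cannot L1-normalise an all-zero degree-{image.degree} image "
            f"({image.n_features} diagram points)"
        )
    return L1NPI(image.grid, image.pixels / total, image.degree)


def mean_l1npi(images: Sequence[L1NPI]) -> L1NPI:
    """Pixelwise arithmetic mean of L1NPIs sharing one grid; sums to 1."""
    if not images:
        raise ValueError("no images to average")
    _check_grids(images)
    mean = np.mean([im.pixels for im in images], axis=0)
    mean /= mean.sum()  # guard against accumulated rounding only
    return L1NPI(
        images[0].grid,
        mean,
        images[0].degree,
        source_frames=sum(im.source_frames for im in images),
    )


def mean_image(images: Sequence[PersistenceImage]) -> PersistenceImage:
    """Pixelwise mean of *raw* images — exposed so the two orderings
    (mean-of-L1NPIs vs L1-normalised mean image) can both be computed."""
    if not images:
        raise ValueError("no images to average")
    _check_grids(images)
    mean = np.mean([im.pixels for im in images], axis=0)
    return PersistenceImage(
        images[0].grid,
        mean,
        images[0].degree,
        n_features=sum(im.n_features for im in images),
    )


def flatten(x: L1NPI | PersistenceImage, label: str = "", frame_index: int = 0) -> DescriptorVector:
    """Row-major flattening (persistence-major: row i spans all births).

    The ordering is ``pixels.reshape(-1)`` of the (ny, nx) matrix, so
    :func:`unflatten` recovers the matrix losslessly — required for turning
    SVM hyperplane coefficients back into images.
    """
    return DescriptorVector(x.pixels.reshape(-1), label=label, frame_index=frame_index)


def unflatten(values: np.ndarray, grid: ImageGrid) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size != grid.nx * grid.ny:
        raise ValueError(
            f"vector length {values.size} != grid size {grid.nx * grid.ny}"
        )
    return values.reshape(grid.ny, grid.nx)


def l1npis_from_images(
    images: Iterable[PersistenceImage], on_empty: str = "skip"
) -> list[L1NPI]:
    """Normalise a batch, skipping (with a warning) all-zero frames.

    Degree-2 diagrams of small clouds can be empty; those frames cannot be
    L1-normalised and are dropped from averages when ``on_empty="skip"``.
    """
    out: list[L1NPI] = []
    n_empty = 0
    for im in images:
        try:
            out.append(normalize(im))
        except EmptyImageError:
            if on_empty != "skip":
                raise
            n_empty += 1
    if n_empty:
        warnings.warn(
            f"skipped {n_empty} empty-diagram frame(s) during L1 normalisation",
            stacklevel=2,
        )
    return out


def descriptor_frame(vectors: Sequence[DescriptorVector]) -> pd.DataFrame:
    """Descriptor matrix (frames × pixels) with ``label`` and ``frame`` columns."""
    data = np.vstack([v.values for v in vectors])
    df = pd.DataFrame(data, columns=[f"px{i}" for i in range(data.shape[1])])
    df.insert(0, "label", [v.label for v in vectors])
    df.insert(1, "frame", [v.frame_index for v in vectors])
    return df
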