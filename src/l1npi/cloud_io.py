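"""Trajectory coordinate I/O and distance-matrix construction.

Point clouds are per-frame sets of atomic coordinates in Ångström. For water
systems the descriptor pipeline operates on the oxygen positions only, so
element symbols are preserved at read time and selected downstream with
:func:`select_element`. Distances are plain Euclidean by default; an explicit
orthorhombic minimum-image mode is available for periodic boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PointCloud",
    "DistanceMatrix",
    "read_xyz_frames",
    "write_xyz_frames",
    "read_pdb_frames",
    "select_element",
    "pairwise_distances",
    "read_distance_csv",
    "write_distance_csv",
]


class ParseError(ValueError):
    """Raised for malformed coordinate files; message names the offending line."""


@dataclass(frozen=True)
class PointCloud:
    """A single frame's 3-D coordinates (Å) with optional orthorhombic box.

    Parameters
    ----------
    coords : (n, 3) float array
        Atomic positions in Å.
    elements : tuple of str, optional
        Element symbol per atom, aligned with ``coords``. May be ``None`` for
        raw geometric clouds (fixtures, lattices) that carry no chemistry.
    box : (3,) float array, optional
        Orthorhombic box edge lengths in Å.
    frame_index : int
        Position of this frame in its source trajectory.
    label : str
        Free-text tag, e.g. the potential or generator name.
    """

    coords: np.ndarray
    elements: tuple[str, ...] | None = None
    box: np.ndarray | None = None
    frame_index: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got shape {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        object.__setattr__(self, "coords", coords)
        if self.elements is not None:
            elements = tuple(self.elements)
            if len(elements) != len(coords):
                raise ValueError(
                    f"{len(elements)} element symbols for {len(coords)} atoms"
                )
            object.__setattr__(self, "elements", elements)
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.shape != (3,) or not np.all(box > 0):
                raise ValueError("box must be three positive edge lengths")
            object.__setattr__(self, "box", box)
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def n_points(self) -> int:
        return len(self.coords)

    def with_label(self, label: str) -> "PointCloud":
        return replace(self, label=label)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances in Å with zero diagonal."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(d)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return self.d.shape[0]


def read_xyz_frames(path: str | Path, label: str = "") -> list[PointCloud]:
    """Read a (multi-frame) XYZ file into one :class:`PointCloud` per frame.

    The standard dialect is expected: an atom-count line, a comment line, then
    ``element x y z`` records. Frames must all carry the same atom count.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    clouds: list[PointCloud] = []
    i = 0
    n_atoms_ref: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].split()[0])
        except (ValueError, IndexError) as exc:
            raise ParseError(
                f"{path}: line {i + 1}: expected an atom-count header, got {lines[i]!r}"
            ) from exc
        if n_atoms_ref is None:
            n_atoms_ref = n_atoms
        elif n_atoms != n_atoms_ref:
            raise ParseError(
                f"{path}: line {i + 1}: frame has {n_atoms} atoms, "
                f"previous frames have {n_atoms_ref}"
            )
        if i + 1 + n_atoms >= len(lines) + 1 and i + 2 + n_atoms > len(lines):
            raise ParseError(
                f"{path}: line {i + 1}: header declares {n_atoms} atoms but the "
                "file ends early"
            )
        body = lines[i + 2 : i + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ParseError(
                f"{path}: line {i + 1}: header declares {n_atoms} atoms but only "
                f"{len(body)} records follow"
            )
        elements: list[str] = []
        coords = np.empty((n_atoms, 3))
        for k, record in enumerate(body):
            parts = record.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {i + 3 + k}: malformed atom record {record!r}"
                )
            elements.append(parts[0])
            try:
                coords[k] = [float(v) for v in parts[1:4]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {i + 3 + k}: non-numeric coordinate in {record!r}"
                ) from exc
        clouds.append(
            PointCloud(
                coords,
                elements=tuple(elements),
                frame_index=len(clouds),
                label=label,
            )
        )
        i += 2 + n_atoms
    if not clouds:
        raise ParseError(f"{path}: no frames found")
    return clouds


def write_xyz_frames(
    clouds: Iterable[PointCloud], path: str | Path, comment: str = ""
) -> None:
    """Write clouds as a multi-frame XYZ file (element defaults to ``X``)."""
    path = Path(path)
    out: list[str] = []
    for cloud in clouds:
        out.append(str(cloud.n_points))
        out.append(comment or cloud.label or f"frame {cloud.frame_index}")
        elements = cloud.elements or ("X",) * cloud.n_points
        for el, (x, y, z) in zip(elements, cloud.coords):
            out.append(f"{el} {x:.10f} {y:.10f} {z:.10f}")
    path.write_text("\n".join(out) + "\n")


def _pdb_element(line: str) -> str:
    # Columns 77-78 hold the element; fall back to the atom-name field.
    el = line[76:78].strip() if len(line) >= 78 else ""
    if el:
        return el.capitalize()
    name = line[12:16].strip()
    name = name.lstrip("0123456789")
    if len(name) >= 2 and name[:2].capitalize() in {"Cl", "Br", "Na", "Mg", "Fe", "Zn"}:
        return name[:2].capitalize()
    return name[:1].upper()


def read_pdb_frames(path: str | Path, label: str = "") -> list[PointCloud]:
    """Read a PDB file; MODEL/ENDMDL delimit frames, CRYST1 populates the box."""
    path = Path(path)
    box: np.ndarray | None = None
    frames: list[tuple[list[str], list[list[float]]]] = []
    current_el: list[str] = []
    current_xyz: list[list[float]] = []
    in_model = False
    for line in path.read_text().splitlines():
        record = line[:6].strip()
        if record == "CRYST1":
            box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
        elif record == "MODEL":
            if current_xyz:
                frames.append((current_el, current_xyz))
                current_el, current_xyz = [], []
            in_model = True
        elif record == "ENDMDL":
            frames.append((current_el, current_xyz))
            current_el, current_xyz = [], []
            in_model = False
        elif record in ("ATOM", "HETATM"):
            current_el.append(_pdb_element(line))
            current_xyz.append(
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            )
    if current_xyz:
        frames.append((current_el, current_xyz))
    frames = [f for f in frames if f[1]]
    if not frames:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return [
        PointCloud(
            np.asarray(xyz), elements=tuple(el), box=box, frame_index=i, label=label
        )
        for i, (el, xyz) in enumerate(frames)
    ]


def select_element(cloud: PointCloud, element: str) -> PointCloud:
    """Return the sub-cloud of atoms matching ``element``, order preserved.

    For an all-water frame selecting ``"O"`` keeps exactly one third of the
    atoms. An empty selection raises rather than silently passing an empty
    cloud downstream.
    """
    if cloud.elements is None:
        raise ValueError("cloud carries no element symbols; cannot select")
    mask = np.array([el.capitalize() == element.capitalize() for el in cloud.elements])
    if not mask.any():
        raise ValueError(
            f"no atoms of element {element!r} in frame {cloud.frame_index}"
        )
    return PointCloud(
        cloud.coords[mask],
        elements=tuple(np.array(cloud.elements)[mask]),
        box=cloud.box,
        frame_index=cloud.frame_index,
        label=cloud.label,
    )


def pairwise_distances(cloud: PointCloud, use_pbc: bool = False) -> DistanceMatrix:
    """Euclidean pairwise distances; optionally orthorhombic minimum image.

    With ``use_pbc`` each displacement component is wrapped to the nearest
    periodic copy, so every entry is at most half the box diagonal.
    """
    if use_pbc:
        if cloud.box is None:
            raise ValueError("use_pbc requested but the cloud has no box")
        delta = cloud.coords[:, None, :] - cloud.coords[None, :, :]
        delta -= cloud.box * np.round(delta / cloud.box)
        d = np.sqrt((delta**2).sum(axis=-1))
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(d)
    return DistanceMatrix(squareform(pdist(cloud.coords)))


def write_distance_csv(dm: DistanceMatrix, path: str | Path) -> None:
    np.savetxt(path, dm.d, delimiter=",", fmt="%.17g")


def read_distance_csv(path: str | Path) -> DistanceMatrix:
    d = np.loadtxt(path, delimiter=",", ndmin=2)
    return DistanceMatrix(d)
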