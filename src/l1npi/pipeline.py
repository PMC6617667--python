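"""End-to-end wiring: point clouds → diagrams → images → descriptor vectors."""

from __future__ import annotations

from typing import Iterable, Sequence

from .cloud_io import PointCloud, pairwise_distances, select_element
from .descriptor import DescriptorVector, L1NPI, flatten, l1npis_from_images
from .image import ImageGrid, PersistenceImage, diagram_to_image
from .vr import PersistenceDiagram, vr_diagram

__all__ = [
    "frames_to_diagrams",
    "diagrams_to_images",
    "frames_to_descriptors",
]


def frames_to_diagrams(
    clouds: Sequence[PointCloud],
    delta_max: float,
    max_degree: int = 1,
    element: str | None = None,
    use_pbc: bool = False,
) -> list[PersistenceDiagram]:
    """Per-frame VR persistence, optionally restricted to one element.

    ``element="O"`` reproduces the oxygen-only point cloud used for water
    frames; ``None`` takes every point (raw geometric clouds).
    """
    diagrams = []
    for cloud in clouds:
        if element is not None and cloud.elements is not None:
            cloud = select_element(cloud, element)
        dm = pairwise_distances(cloud, use_pbc=use_pbc)
        diagrams.append(vr_diagram(dm, delta_max, max_degree=max_degree))
    return diagrams


def diagrams_to_images(
    diagrams: Iterable[PersistenceDiagram], degree: int, grid: ImageGrid
) -> list[PersistenceImage]:
    return [diagram_to_image(dg, degree, grid) for dg in diagrams]


def frames_to_descriptors(
    clouds: Sequence[PointCloud],
    delta_max: float,
    degree: int,
    grid: ImageGrid,
    label: str,
    element: str | None = None,
    use_pbc: bool = False,
    normalised: bool = True,
) -> list[DescriptorVector]:
    """Full descriptor pipeline for one labelled ensemble.

    With ``normalised=False`` the raw persistence images are flattened
    instead of L1NPIs — the comparison object for size-independence studies.
    """
    diagrams = frames_to_diagrams(
        clouds, delta_max, max_degree=degree, element=element, use_pbc=use_pbc
    )
    images = diagrams_to_images(diagrams, degree, grid)
    if normalised:
        items: Sequence[L1NPI | PersistenceImage] = l1npis_from_images(images)
    else:
        items = images
    return [
        flatten(im, label=label, frame_index=i) for i, im in enumerate(items)
    ]
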