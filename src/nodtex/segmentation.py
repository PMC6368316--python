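"""Segmentation refinement: the parenchyma-nulling rule.

A hand-drawn ROI around a pulmonary nodule inevitably includes aerated
lung.  The analysis pipeline therefore discards every in-mask voxel with
attenuation below a Hounsfield floor (default -500 HU) before any
feature is computed; the retained voxel set — the :class:`NoduleSegment`
— is the single substrate for intensity, co-occurrence and morphology
features alike.  Voxels at exactly the floor are retained ("below the
floor" is read as a strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CongruenceError, EmptySegmentError, ValidationError
from .volume_io import CTVolume, NoduleMask

DEFAULT_HU_FLOOR = -500.0


@dataclass
class NoduleSegment:
    """The retained (in-mask, >= HU floor) voxels of one nodule.

    ``coords`` is an (n, 3) integer array of (z, y, x) grid indices into
    the original volume; ``hu`` the matching attenuation values.
    """

    coords: np.ndarray
    hu: np.ndarray
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    nodule_id: str = "nodule"
    hu_floor: float = DEFAULT_HU_FLOOR
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=np.intp))
        self.hu = np.asarray(self.hu, dtype=float)
        if len(self.coords) != len(self.hu):
            raise ValidationError("coords and hu lengths differ")
        if len(self.hu) == 0:
            raise EmptySegmentError("segment has no voxels", nodule_id=self.nodule_id)
        self.spacing = tuple(float(s) for s in self.spacing)

    def __len__(self) -> int:
        return len(self.hu)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def dense_mask(self) -> np.ndarray:
        """Binary grid of the retained set at the original volume shape."""
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.coords.T)] = True
        return m

    def dense_hu(self, fill: float = np.nan) -> np.ndarray:
        """HU grid with ``fill`` outside the retained set."""
        g = np.full(self.shape, fill, dtype=float)
        g[tuple(self.coords.T)] = self.hu
        return g


def refine_mask(
    volume: CTVolume,
    mask: NoduleMask,
    hu_floor: float = DEFAULT_HU_FLOOR,
) -> NoduleSegment:
    """Null parenchyma: keep in-mask voxels with HU >= ``hu_floor``.

    Raises :class:`EmptySegmentError` (carrying the nodule id) when every
    voxel falls below the floor — an empty segment is an error, not a
    degenerate value.
    """
    mask.check_congruent(volume)
    if not mask.voxels.any():
        raise EmptySegmentError("input mask has no foreground", nodule_id=mask.nodule_id)
    keep = mask.voxels & (volume.voxels >= hu_floor)
    if not keep.any():
        raise EmptySegmentError(
            f"all voxels of {mask.nodule_id!r} fall below the {hu_floor} HU floor",
            nodule_id=mask.nodule_id,
        )
    coords = np.argwhere(keep)
    return NoduleSegment(
        coords=coords,
        hu=volume.voxels[keep].astype(float),
        spacing=volume.spacing,
        shape=volume.shape,
        nodule_id=mask.nodule_id,
        hu_floor=float(hu_floor),
    )


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def largest_component(segment: NoduleSegment, connectivity: int = 26) -> NoduleSegment:
    """Keep the largest connected component of the retained set.

    Ties are broken deterministically by the component containing the
    lexicographically smallest voxel.  Off by default in the pipeline:
    the nulling rule alone defines the published segment.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValidationError(f"connectivity must be one of 6/18/26, got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, n = ndimage.label(segment.dense_mask(), structure=structure)
    if n <= 1:
        return segment
    sizes = ndimage.sum_labels(np.ones(labels.shape), labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) == 1:
        winner = candidates[0]
    else:
        # smallest lexicographic seed voxel among tied components
        seeds = []
        for lab in candidates:
            pts = np.argwhere(labels == lab)
            order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0]))
            seeds.append(tuple(pts[order[0]]))
        winner = candidates[min(range(len(seeds)), key=seeds.__getitem__)]
    keep = labels[tuple(segment.coords.T)] == winner
    return NoduleSegment(
        coords=segment.coords[keep],
        hu=segment.hu[keep],
        spacing=segment.spacing,
        shape=segment.shape,
        nodule_id=segment.nodule_id,
        hu_floor=segment.hu_floor,
        warnings=list(segment.warnings),
    )
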