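"""Emulation of conventional single-slice PACS measurements.

The comparison arm of the analysis: a radiologist measuring a nodule on
one representative axial section with a ruler (long diameter) and a
circular ROI (mean/SD attenuation).  Crucially the circular ROI is
placed on the *unmasked* image — no parenchyma nulling — so for small
nodules it dilutes the attenuation with surrounding aerated lung.  That
dilution is exactly the weakness volumetric analysis removes, so the
emulation keeps it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .segmentation import NoduleSegment
from .volume_io import CTVolume

DEFAULT_ROI_FACTOR = 0.8

#: The lung-window-visible halo extends past the solid support by roughly
#: the partial-volume width; the drawn circle follows that visible rim.
DEFAULT_RIM_MARGIN_MM = 1.5


@dataclass
class ConventionalFeatures:
    conventional_long_diameter: float  # mm
    conventional_mean_attenuation: float  # HU
    conventional_attenuation_sd: float  # HU
    representative_slice: int


def representative_slice(segment: NoduleSegment) -> int:
    """Axial slice index with the largest in-plane retained area.

    Ties break to the lowest index.
    """
    counts = np.bincount(segment.coords[:, 0], minlength=segment.shape[0])
    return int(np.argmax(counts))


def long_diameter(segment: NoduleSegment, slice_index: int) -> float:
    """Maximum pairwise in-plane distance (mm) between retained voxel centers."""
    pts = _inplane_mm(segment, slice_index)
    if len(pts) == 1:
        return 0.0
    # max pairwise distance via squared-norm expansion on the hull-free set;
    # nodule slices are small enough for the O(n^2) scan
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def conventional_measurements(
    volume: CTVolume,
    segment: NoduleSegment,
    slice_index: int | None = None,
    roi_factor: float = DEFAULT_ROI_FACTOR,
    rim_margin_mm: float = DEFAULT_RIM_MARGIN_MM,
) -> ConventionalFeatures:
    """Single-slice long diameter and circular-ROI attenuation statistics.

    The circular ROI is centered at the in-plane centroid of the
    retained voxels with radius ``roi_factor`` times half the visible
    extent (long diameter plus the ``rim_margin_mm`` partial-volume
    halo), and is evaluated on the raw image without the HU floor —
    for small nodules the circle unavoidably samples parenchyma, the
    dilution the volumetric analysis removes.
    """
    if not (0 < roi_factor):
        raise ValidationError("roi_factor must be positive")
    if rim_margin_mm < 0:
        raise ValidationError("rim_margin_mm must be non-negative")
    if slice_index is None:
        slice_index = representative_slice(segment)
    if not (0 <= slice_index < segment.shape[0]):
        raise ValidationError(f"slice index {slice_index} outside volume")
    pts = _inplane_mm(segment, slice_index)
    ld = long_diameter(segment, slice_index)
    center = pts.mean(axis=0)
    radius = max(
        roi_factor * (ld / 2.0 + rim_margin_mm), max(volume.spacing[1:])
    )  # at least one voxel
    sz, sy, sx = volume.spacing
    ny, nx = volume.shape[1:]
    yy, xx = np.meshgrid(np.arange(ny) * sy, np.arange(nx) * sx, indexing="ij")
    inside = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    vals = volume.voxels[slice_index][inside].astype(float)
    if vals.size == 0:
        raise ValidationError("circular ROI contains no voxels")
    return ConventionalFeatures(
        conventional_long_diameter=ld,
        conventional_mean_attenuation=float(vals.mean()),
        conventional_attenuation_sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        representative_slice=int(slice_index),
    )


def _inplane_mm(segment: NoduleSegment, slice_index: int) -> np.ndarray:
    sel = segment.coords[:, 0] == slice_index
    if not sel.any():
        raise ValidationError(f"slice {slice_index} contains no retained voxel")
    yx = segment.coords[sel][:, 1:].astype(float)
    return yx * np.array(segment.spacing[1:])
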