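"""First-order histogram statistics and 3D GLCM texture features.

First-order statistics (mean attenuation, SD, variance, skewness, excess
kurtosis) are computed over the retained HU values of a segment.  The
second-order features come from a single gray-level co-occurrence matrix
(GLCM) accumulated over the 13 unique 3D grid directions at Chebyshev
distance 1, counted symmetrically and normalised to sum 1; pairs with
either endpoint outside the retained set are excluded.

Quantization is deliberately fine: the default bin width is 1 HU from
the segment minimum, i.e. gray levels essentially *are* HU values.  The
magnitudes this produces (ASM and IDM of order 1e-3, contrast of order
1e4-1e5 HU^2, entropy of a few nats) match the scale reported for
volumetric nodule texture; coarse 32- or 64-level binning would not.

"GLCM moments" is implemented as the first absolute difference moment
``sum_ij P(i,j) |i-j|``; the quantity has no universally fixed
definition, and this choice is documented in docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    InsufficientSampleError,
    NoPairsError,
    UndefinedMomentError,
    ValidationError,
)
from .segmentation import NoduleSegment

#: The 13 unique grid directions at Chebyshev distance 1 (one per +/- pair),
#: canonical form: first nonzero component positive, (z, y, x) order.
OFFSETS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: Axial in-plane + through-plane axis directions only.
OFFSETS_AXIAL3: tuple[tuple[int, int, int], ...] = ((0, 0, 1), (0, 1, 0), (1, 0, 0))


@dataclass
class FirstOrderFeatures:
    mean_attenuation: float
    attenuation_sd: float
    attenuation_variance: float
    skewness: float
    kurtosis: float  # excess


def first_order(segment: NoduleSegment, ddof: int = 1) -> FirstOrderFeatures:
    """First-order statistics of the retained HU values.

    Variance/SD use ``ddof`` (default 1, the sample convention);
    skewness and kurtosis are the conventional biased standardized
    moments ``m3/m2^1.5`` and ``m4/m2^2 - 3`` with central moments
    weighted 1/n.
    """
    x = segment.hu
    n = len(x)
    if n < 2:
        raise InsufficientSampleError(f"need >= 2 voxels for SD/variance, got {n}")
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=ddof))
    sd = math.sqrt(var)
    if n < 3:
        raise InsufficientSampleError(f"need >= 3 voxels for skewness/kurtosis, got {n}")
    d = x - mean
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        raise UndefinedMomentError("skewness/kurtosis undefined: zero variance")
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return FirstOrderFeatures(
        mean_attenuation=mean,
        attenuation_sd=sd,
        attenuation_variance=var,
        skewness=m3 / m2**1.5,
        kurtosis=m4 / m2**2 - 3.0,
    )


@dataclass
class QuantizedGrid:
    """Integer gray-level grid; -1 marks voxels outside the retained set."""

    levels: np.ndarray
    n_levels: int
    bin_width: float
    hu_floor: float  # HU value of the lower edge of level 0

    def bin_center(self, level: np.ndarray | int) -> np.ndarray | float:
        return self.hu_floor + (np.asarray(level) + 0.5) * self.bin_width


def quantize(segment: NoduleSegment, bin_width: float = 1.0) -> QuantizedGrid:
    """Quantize retained HU into levels: floor((HU - min HU)/bin_width)."""
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    hu_min = float(segment.hu.min())
    lv = np.floor((segment.hu - hu_min) / bin_width).astype(np.int64)
    grid = np.full(segment.shape, -1, dtype=np.int64)
    grid[tuple(segment.coords.T)] = lv
    return QuantizedGrid(
        levels=grid,
        n_levels=int(lv.max()) + 1,
        bin_width=float(bin_width),
        hu_floor=hu_min,
    )


@dataclass
class GLCMMatrix:
    """Sparse normalized co-occurrence matrix.

    ``i``, ``j`` are gray-level pair indices with probabilities ``p``
    (summing to 1); stored sparse because fine HU quantization can span
    thousands of levels.
    """

    i: np.ndarray
    j: np.ndarray
    p: np.ndarray
    n_levels: int
    bin_width: float
    offsets: tuple[tuple[int, int, int], ...]
    symmetric: bool

    def to_dense(self) -> np.ndarray:
        if self.n_levels > 4096:
            raise ValidationError(f"refusing dense {self.n_levels}^2 matrix")
        m = np.zeros((self.n_levels, self.n_levels))
        m[self.i, self.j] = self.p
        return m


def glcm(
    quantized: QuantizedGrid,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13,
    symmetric: bool = True,
) -> GLCMMatrix:
    """Accumulate co-occurrence counts over all offsets into one matrix.

    Only pairs with both endpoints inside the retained set count; with
    ``symmetric`` each pair is counted in both orderings.
    """
    grid = quantized.levels
    pair_i: list[np.ndarray] = []
    pair_j: list[np.ndarray] = []
    for off in offsets:
        src = _shift_slices(grid.shape, off, source=True)
        dst = _shift_slices(grid.shape, off, source=False)
        a = grid[src]
        b = grid[dst]
        ok = (a >= 0) & (b >= 0)
        pair_i.append(a[ok])
        pair_j.append(b[ok])
    ii = np.concatenate(pair_i)
    jj = np.concatenate(pair_j)
    if len(ii) == 0:
        raise NoPairsError("no valid voxel pair for any offset (single voxel?)")
    if symmetric:
        ii, jj = np.concatenate([ii, jj]), np.concatenate([jj, ii])
    n = quantized.n_levels
    keys, counts = np.unique(ii * n + jj, return_counts=True)
    p = counts / counts.sum()
    return GLCMMatrix(
        i=(keys // n).astype(np.int64),
        j=(keys % n).astype(np.int64),
        p=p,
        n_levels=n,
        bin_width=quantized.bin_width,
        offsets=tuple(offsets),
        symmetric=symmetric,
    )


def _shift_slices(shape, offset, source: bool):
    """Slices selecting voxel pairs separated by ``offset``."""
    sl = []
    for size, d in zip(shape, offset):
        if source:
            sl.append(slice(max(0, -d), min(size, size - d)))
        else:
            sl.append(slice(max(0, d), min(size, size + d)))
    return tuple(sl)


@dataclass
class GLCMFeatures:
    glcm_moments: float  # first absolute difference moment, sum P|i-j|
    glcm_asm: float
    glcm_idm: float
    glcm_contrast: float
    glcm_entropy: float  # nats by default


def glcm_features(matrix: GLCMMatrix, entropy_base: float = math.e) -> GLCMFeatures:
    """Scalar texture features of a normalized GLCM.

    ASM = sum P^2; IDM = sum P/(1+(i-j)^2); contrast = sum P (i-j)^2;
    entropy = -sum P log P (0 log 0 = 0); moments = sum P |i-j|.
    """
    p = matrix.p
    diff = (matrix.i - matrix.j).astype(float)
    asm = float(np.sum(p**2))
    idm = float(np.sum(p / (1.0 + diff**2)))
    contrast = float(np.sum(p * diff**2))
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log(p[nz])) / math.log(entropy_base))
    moments = float(np.sum(p * np.abs(diff)))
    return GLCMFeatures(
        glcm_moments=moments,
        glcm_asm=asm,
        glcm_idm=idm,
        glcm_contrast=contrast,
        glcm_entropy=entropy,
    )


def glcm_features_per_direction(
    quantized: QuantizedGrid,
    offsets: tuple[tuple[int, int, int], ...] = OFFSETS_13,
    symmetric: bool = True,
    entropy_base: float = math.e,
) -> GLCMFeatures:
    """Alternative convention: one GLCM per direction, features averaged.

    Offsets yielding no valid pair are skipped; raises if none yields any.
    """
    per: list[GLCMFeatures] = []
    for off in offsets:
        try:
            per.append(glcm_features(glcm(quantized, (off,), symmetric), entropy_base))
        except NoPairsError:
            continue
    if not per:
        raise NoPairsError("no valid voxel pair for any offset")
    return GLCMFeatures(
        **{
            k: float(np.mean([getattr(f, k) for f in per]))
            for k in GLCMFeatures.__dataclass_fields__
        }
    )
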