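"""Synthetic CT nodule phantoms and feature-level cohorts.

Two generators cover the two levels at which the pipeline can be
exercised without patient data:

* **Voxel phantoms** — a single nodule (sphere, ellipsoid or lobulated
  blob) of known diameter and attenuation, embedded in aerated-lung
  background well below the -500 HU floor, with optional calcifications
  (random interior voxels pushed to bone-range HU) and Gaussian blur as
  a partial-volume surrogate.  Ground truth (analytic volume, diameter,
  generating attenuation moments) travels with the phantom.

* **Feature cohorts** — per-nodule feature vectors drawn from group
  Gaussians (optionally correlated), parameterised by default with the
  published osteosarcoma summary statistics in
  :mod:`nodtex.cohort_params`.

A deterministic 42-nodule fixture cohort mirroring the study
composition (24 metastatic / 18 non-metastatic; 25 small non-calcified
nodules splitting 7 / 18) is committed with the package and loaded by
:func:`fixture_cohort`.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from . import cohort_params as cp
from .errors import DegenerateMaskError, ValidationError
from .volume_io import CTVolume, NoduleMask, validate_cohort

SHAPES = ("sphere", "ellipsoid", "lobulated")
# fixed principal-axis ratios for the ellipsoid, volume-normalised
_ELLIPSOID_RATIOS = (0.7, 1.0, 1.43)


@dataclass
class PhantomSpec:
    """Generating parameters for a single-nodule CT phantom."""

    shape: str = "sphere"
    diameter_mm: float = 10.0
    nodule_hu_mean: float = 50.0
    nodule_hu_sd: float = 150.0
    calcification_fraction: float = 0.0
    calcification_hu_range: tuple[float, float] = (200.0, 800.0)
    parenchyma_hu_mean: float = -850.0
    parenchyma_hu_sd: float = 40.0
    blur_mm: float = 0.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    margin_mm: float = 5.0
    seed: int = 0
    nodule_id: str = "phantom"

    def validate(self) -> None:
        if self.shape not in SHAPES:
            raise ValidationError(f"shape must be one of {SHAPES}, got {self.shape!r}")
        if self.diameter_mm <= 0:
            raise ValidationError("diameter must be positive")
        if not (0.0 <= self.calcification_fraction <= 1.0):
            raise ValidationError("calcification fraction must lie in [0, 1]")
        if self.blur_mm < 0:
            raise ValidationError("blur width must be non-negative")
        if self.parenchyma_hu_mean >= -500.0:
            raise ValidationError(
                "parenchyma mean must be below -500 HU so background is nulled"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing components must be positive")


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, NoduleMask, dict]:
    """Build (volume, mask, ground_truth) for one nodule phantom.

    The mask is the pre-blur nodule support; blurring affects only HU.
    ``ground_truth`` records the analytic volume and equivalent diameter
    (for the lobulated shape, the discrete support volume stands in) and
    the generating attenuation parameters.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.spacing, dtype=float)
    extent = spec.diameter_mm + 2 * spec.margin_mm
    shape = tuple(int(np.ceil(extent / s)) | 1 for s in spacing)  # odd → exact center
    if any(n * s < spec.diameter_mm for n, s in zip(shape, spacing)):
        raise ValidationError("nodule larger than the grid; increase margin")
    center = (np.array(shape) - 1) / 2.0 * spacing
    zz, yy, xx = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    r = spec.diameter_mm / 2.0

    if spec.shape == "sphere":
        support = _ball(zz, yy, xx, center, (r, r, r))
        analytic_volume = 4.0 / 3.0 * np.pi * r**3
    elif spec.shape == "ellipsoid":
        semi = r * np.array(_ELLIPSOID_RATIOS)
        semi *= (r**3 / np.prod(semi)) ** (1.0 / 3.0)  # keep the equivalent volume
        support = _ball(zz, yy, xx, center, semi)
        analytic_volume = 4.0 / 3.0 * np.pi * float(np.prod(semi))
    else:  # lobulated: central sphere + 2-4 offset lobes
        support = _ball(zz, yy, xx, center, (0.8 * r,) * 3)
        for _ in range(rng.integers(2, 5)):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            lobe_c = center + direction * 0.6 * r
            support |= _ball(zz, yy, xx, lobe_c, (0.45 * r,) * 3)
        analytic_volume = None

    if not support.any():
        raise ValidationError("nodule support empty at this spacing")

    hu = rng.normal(spec.parenchyma_hu_mean, spec.parenchyma_hu_sd, size=shape)
    hu[support] = rng.normal(spec.nodule_hu_mean, spec.nodule_hu_sd, size=int(support.sum()))

    n_calc = int(round(spec.calcification_fraction * support.sum()))
    if n_calc > 0:
        interior = ndimage.binary_erosion(support)
        pool = np.argwhere(interior if interior.any() else support)
        pick = pool[rng.choice(len(pool), size=min(n_calc, len(pool)), replace=False)]
        lo, hi = spec.calcification_hu_range
        hu[tuple(pick.T)] = rng.uniform(lo, hi, size=len(pick))

    if spec.blur_mm > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.blur_mm / spacing)

    voxel_vol = float(np.prod(spacing))
    disc_volume = float(support.sum()) * voxel_vol
    gt_volume = analytic_volume if analytic_volume is not None else disc_volume
    ground_truth = {
        "analytic_volume_mm3": gt_volume,
        "analytic_equivalent_diameter_mm": float((6.0 * gt_volume / np.pi) ** (1 / 3)),
        "support_voxels": int(support.sum()),
        "support_volume_mm3": disc_volume,
        "calcified": n_calc > 0,
        **{f"spec_{k}": v for k, v in asdict(spec).items()},
    }
    volume = CTVolume(voxels=hu, spacing=tuple(spacing))
    mask = NoduleMask(voxels=support, spacing=tuple(spacing), nodule_id=spec.nodule_id)
    return volume, mask, ground_truth


def _ball(zz, yy, xx, center, semi) -> np.ndarray:
    cz, cy, cx = center
    az, ay, ax = semi
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


PERTURBATIONS = ("dilate", "erode", "boundary-jitter")


def generate_second_observer_mask(
    mask: NoduleMask,
    perturbation: str = "boundary-jitter",
    magnitude: int = 1,
    seed: int = 0,
) -> NoduleMask:
    """Emulate an independent second observer by perturbing a mask.

    ``dilate``/``erode`` apply ``magnitude`` morphological iterations;
    ``boundary-jitter`` keeps the ``magnitude``-eroded core and tosses a
    fair coin for every voxel in the boundary band between erosion and
    dilation.  Raises :class:`DegenerateMaskError` if the result is empty.
    """
    if perturbation not in PERTURBATIONS:
        raise ValidationError(f"perturbation must be one of {PERTURBATIONS}")
    if magnitude < 0:
        raise ValidationError("magnitude must be >= 0")
    m = mask.voxels
    if magnitude == 0:
        return NoduleMask(m.copy(), mask.spacing, nodule_id=mask.nodule_id + "_obs2")
    if perturbation == "dilate":
        out = ndimage.binary_dilation(m, iterations=magnitude)
    elif perturbation == "erode":
        out = ndimage.binary_erosion(m, iterations=magnitude)
    else:
        rng = np.random.default_rng(seed)
        core = ndimage.binary_erosion(m, iterations=magnitude)
        band = ndimage.binary_dilation(m, iterations=magnitude) & ~core
        out = core | (band & (rng.random(m.shape) < 0.5))
    if not out.any():
        raise DegenerateMaskError(
            f"{perturbation} by {magnitude} emptied mask {mask.nodule_id!r}"
        )
    return NoduleMask(out, mask.spacing, nodule_id=mask.nodule_id + "_obs2")


@dataclass
class CohortSpec:
    """Group Gaussians for feature-level cohort simulation.

    ``params`` maps feature name -> ((mean, sd) metastatic, (mean, sd)
    non-metastatic); ``correlation`` is an optional common within-group
    correlation matrix over ``features order``.
    """

    params: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: dict(cp.TOTAL_GROUP_PARAMS)
    )
    n_metastasis: int = cp.TOTAL_GROUP_SIZES[0]
    n_non_metastasis: int = cp.TOTAL_GROUP_SIZES[1]
    correlation: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_metastasis < 2 or self.n_non_metastasis < 2:
            raise ValidationError("group sizes must be >= 2")
        for name, ((m1, s1), (m2, s2)) in self.params.items():
            if s1 < 0 or s2 < 0:
                raise ValidationError(f"negative SD for feature {name!r}")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len(self.params)
            if c.shape != (k, k) or not np.allclose(c, c.T):
                raise ValidationError("correlation must be a symmetric k x k matrix")
            try:
                np.linalg.cholesky(c)
            except np.linalg.LinAlgError as exc:
                raise ValidationError("correlation matrix not positive definite") from exc


def generate_feature_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a labelled cohort table from the group Gaussians.

    Features are independent within group unless a correlation structure
    is supplied (then a Gaussian copula with the given correlation and
    the per-feature marginal means/SDs).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    feats = list(spec.params)
    rows = []
    for label, n in (
        (cp.LABEL_METASTASIS, spec.n_metastasis),
        (cp.LABEL_NON_METASTASIS, spec.n_non_metastasis),
    ):
        g = 0 if label == cp.LABEL_METASTASIS else 1
        means = np.array([spec.params[f][g][0] for f in feats])
        sds = np.array([spec.params[f][g][1] for f in feats])
        if spec.correlation is None:
            z = rng.standard_normal((n, len(feats)))
        else:
            chol = np.linalg.cholesky(np.asarray(spec.correlation, dtype=float))
            z = rng.standard_normal((n, len(feats))) @ chol.T
        block = pd.DataFrame(means + z * sds, columns=feats)
        block.insert(0, "label", label)
        rows.append(block)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "nodule_id", [f"sim_{i:03d}" for i in range(len(out))])
    out["calcified"] = False
    if "effective_diameter" in out.columns:
        out["subgroup"] = (out["effective_diameter"] <= cp.SUBGROUP_DIAMETER_MM) & ~out[
            "calcified"
        ]
    else:
        out["subgroup"] = False
    return out


def fixture_cohort() -> pd.DataFrame:
    """The committed deterministic 42-nodule cohort.

    24 metastatic / 18 non-metastatic; exactly 7 metastatic and all 18
    non-metastatic nodules are small (effective diameter <= 5 mm) and
    non-calcified, so the subgroup filter yields 25 nodules.
    """
    ref = importlib.resources.files("nodtex") / "data" / "fixture_cohort.csv"
    with importlib.resources.as_file(ref) as path:
        return validate_cohort(pd.read_csv(path))
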