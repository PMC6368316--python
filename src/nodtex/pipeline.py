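"""Pipeline orchestration: simulate -> extract -> analyze.

``run_extract`` turns (volume, mask) pairs into the per-nodule feature
table; ``run_analyze`` runs the full statistical chain on a cohort:
univariate group comparison, collinearity pruning, backward logistic
regression, ROC/Youden for the surviving predictors, then the same
chain on the small non-calcified subgroup, and (when conventional
columns are present) paired DeLong comparisons of volumetric vs
conventional markers.  Both are pure functions of (inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from . import cohort_params as cp
from .conventional_features import conventional_measurements, representative_slice
from .errors import EmptySegmentError, NodtexError, ValidationError
from .features_intensity import (
    OFFSETS_13,
    OFFSETS_AXIAL3,
    first_order,
    glcm,
    glcm_features,
    quantize,
)
from .features_morphology import morphology_features
from .model_eval import compare_auc_delong, fit_logistic_backward, roc
from .segmentation import largest_component, refine_mask
from .stats_compare import compare_all_features, icc_two_observer, prune_collinear
from .volume_io import CTVolume, NoduleMask, validate_cohort

log = logging.getLogger("nodtex")

_OFFSET_SETS = {"13dir": OFFSETS_13, "axial3": OFFSETS_AXIAL3}


@dataclass
class RunConfig:
    """Every knob of the pipeline, with the published defaults."""

    hu_floor: float = -500.0
    keep_largest_component: bool = False
    bin_width: float = 1.0
    offsets: str = "13dir"
    entropy_base: float = float(np.e)
    surface_method: str = "mesh"
    with_conventional: bool = False
    roi_factor: float = 0.8
    roi_rim_mm: float = 1.5
    subgroup_diameter_mm: float = cp.SUBGROUP_DIAMETER_MM
    test_variant: str = "pooled"
    significance: float = 0.05
    r_threshold: float = 0.8
    vif_threshold: float = 5.0
    removal_p: float = 0.10
    or_scale: str = "unit"
    seed: int = 0

    def __post_init__(self):
        if self.subgroup_diameter_mm <= 0:
            raise ValidationError("subgroup diameter cut-off must be positive")
        if self.offsets not in _OFFSET_SETS:
            raise ValidationError(f"offsets must be one of {sorted(_OFFSET_SETS)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def extract_features(
    volume: CTVolume,
    mask: NoduleMask,
    config: RunConfig | None = None,
) -> dict[str, float]:
    """All 15 features (plus optional conventional columns) for one nodule."""
    config = config or RunConfig()
    segment = refine_mask(volume, mask, hu_floor=config.hu_floor)
    if config.keep_largest_component:
        segment = largest_component(segment)
    fo = first_order(segment)
    q = quantize(segment, bin_width=config.bin_width)
    g = glcm_features(glcm(q, offsets=_OFFSET_SETS[config.offsets]), config.entropy_base)
    morph = morphology_features(segment, surface_method=config.surface_method)
    row: dict[str, float] = {**asdict(fo), **asdict(g), **asdict(morph)}
    if config.with_conventional:
        conv = conventional_measurements(
            volume, segment, representative_slice(segment),
            roi_factor=config.roi_factor, rim_margin_mm=config.roi_rim_mm,
        )
        row.update(asdict(conv))
    return row


def run_extract(
    pairs: list[tuple[CTVolume, NoduleMask]],
    config: RunConfig | None = None,
    labels: dict[str, str] | None = None,
    calcified: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Feature table over nodules; empty segments are skipped with a reason.

    ``labels``/``calcified`` map nodule ids to group label and
    calcification flag (defaults: "unknown", False).
    """
    config = config or RunConfig()
    rows, skipped = [], []
    for volume, mask in pairs:
        nid = mask.nodule_id
        t0 = time.perf_counter()
        try:
            row = extract_features(volume, mask, config)
        except EmptySegmentError as exc:
            log.warning("extract %s: skipped (%s)", nid, exc)
            skipped.append((nid, str(exc)))
            continue
        log.info("extract %s: ok (%.2f s)", nid, time.perf_counter() - t0)
        row["nodule_id"] = nid
        rows.append(row)
    if not rows:
        raise NodtexError(f"all {len(skipped)} nodules were skipped")
    table = pd.DataFrame(rows)
    table["label"] = [
        (labels or {}).get(n, "unknown") for n in table["nodule_id"]
    ]
    table["calcified"] = [
        bool((calcified or {}).get(n, False)) for n in table["nodule_id"]
    ]
    table["subgroup"] = (
        table["effective_diameter"] <= config.subgroup_diameter_mm
    ) & ~table["calcified"]
    table.attrs["skipped"] = skipped
    return validate_cohort(table)


def subgroup_filter(cohort: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """Small non-calcified nodules: effective diameter <= cut-off, not calcified."""
    config = config or RunConfig()
    keep = (cohort["effective_diameter"] <= config.subgroup_diameter_mm) & ~cohort[
        "calcified"
    ].astype(bool)
    return cohort[keep].reset_index(drop=True)


def icc_table(
    cohort1: pd.DataFrame, cohort2: pd.DataFrame, features: list[str] | None = None
) -> pd.DataFrame:
    """Two-observer reproducibility table (ICC(2,1) per feature)."""
    features = features or list(cp.FEATURE_NAMES)
    a = cohort1.sort_values("nodule_id").reset_index(drop=True)
    b = cohort2.sort_values("nodule_id").reset_index(drop=True)
    if not (a["nodule_id"] == b["nodule_id"]).all():
        raise ValidationError("observer cohorts must cover the same nodules")
    rows = []
    for f in features:
        r = icc_two_observer(a[f], b[f])
        rows.append(
            {"feature": f, "icc": r.icc, "ci_lower": r.ci_lower,
             "ci_upper": r.ci_upper, "band": r.band}
        )
    return pd.DataFrame(rows)


def _analysis_block(cohort: pd.DataFrame, config: RunConfig) -> dict:
    """One comparison->pruning->logistic->ROC pass over a cohort."""
    comparison = compare_all_features(
        cohort, list(cp.FEATURE_NAMES), variant=config.test_variant
    )
    candidates = comparison.loc[
        comparison["p"] < config.significance, "feature"
    ].tolist()
    block: dict = {
        "n": int(len(cohort)),
        "n_metastasis": int((cohort["label"] == cp.LABEL_METASTASIS).sum()),
        "n_non_metastasis": int((cohort["label"] == cp.LABEL_NON_METASTASIS).sum()),
        "comparison": comparison.to_dict(orient="records"),
        "candidates": candidates,
    }
    if len(candidates) >= 2:
        pruning = prune_collinear(
            cohort, candidates, config.r_threshold, config.vif_threshold,
            variant=config.test_variant,
        )
        block["pruning"] = {
            "clusters": pruning.clusters,
            "retained": pruning.retained,
            "excluded": pruning.excluded,
            "vif": pruning.vif,
            "vif_flagged": pruning.vif_flagged,
        }
        predictors = pruning.retained
    else:
        block["pruning"] = None
        predictors = candidates
    if predictors:
        model = fit_logistic_backward(
            cohort, predictors, removal_p=config.removal_p, or_scale=config.or_scale
        )
        block["logistic"] = {
            "predictors": model.predictors,
            "coefficients": model.coefficients,
            "odds_ratios": model.odds_ratios,
            "or_ci": {k: list(v) for k, v in model.or_ci.items()},
            "p_values": model.p_values,
            "elimination_trace": model.elimination_trace,
            "converged": model.converged,
            "separation_flag": model.separation_flag,
        }
        rocs = {}
        y = (cohort["label"] == cp.LABEL_METASTASIS).to_numpy(int)
        for pred in model.predictors:
            r = roc(cohort[pred].to_numpy(float), y)
            rocs[pred] = {
                "auc": r.auc,
                "auc_ci": list(r.auc_ci),
                "optimal_threshold": r.optimal_threshold,
                "sensitivity": r.optimal_sensitivity,
                "specificity": r.optimal_specificity,
            }
        block["roc"] = rocs
    else:
        block["logistic"] = None
        block["roc"] = {}
    return block


def run_analyze(
    cohort: pd.DataFrame,
    config: RunConfig | None = None,
    observer2: pd.DataFrame | None = None,
) -> dict:
    """The full statistical report (JSON-serializable dict)."""
    config = config or RunConfig()
    cohort = validate_cohort(cohort)
    report: dict = {"config": asdict(config)}
    report["total"] = _analysis_block(cohort, config)
    sub = subgroup_filter(cohort, config)
    if sub["label"].nunique() < 2 or any(
        (sub["label"] == lab).sum() < 2
        for lab in (cp.LABEL_METASTASIS, cp.LABEL_NON_METASTASIS)
    ):
        log.warning("subgroup has a single class or <2 per group; skipped")
        report["subgroup"] = {"skipped": "subgroup lacks two adequately sized classes",
                              "n": int(len(sub))}
    else:
        report["subgroup"] = _analysis_block(sub, config)
    conv_pairs = [
        ("mean_attenuation", "conventional_mean_attenuation"),
        ("effective_diameter", "conventional_long_diameter"),
    ]
    if all(c in cohort.columns for _, c in conv_pairs):
        y = (cohort["label"] == cp.LABEL_METASTASIS).to_numpy(int)
        comps = {}
        for vol_col, conv_col in conv_pairs:
            c = compare_auc_delong(
                cohort[vol_col].to_numpy(float), cohort[conv_col].to_numpy(float), y
            )
            comps[f"{vol_col}_vs_{conv_col}"] = {
                "auc_volumetric": c.auc_a, "auc_conventional": c.auc_b,
                "difference": c.difference, "z": c.z, "p": c.p,
            }
        report["conventional_comparison"] = comps
    if observer2 is not None:
        report["icc"] = icc_table(cohort, observer2).to_dict(orient="records")
    return _jsonable(report)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
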