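"""Multivariate model and discrimination analysis.

Backward-elimination logistic regression (maximum likelihood, Wald
removal at p > 0.10 by default) yields adjusted odds ratios per unit of
each predictor (per HU, per mm) with 95% Wald CIs.  ROC analysis places
thresholds at midpoints between consecutive unique marker values, takes
AUC as the Mann-Whitney concordance probability (ties count one half),
picks the operating point by the Youden index (ties: higher
specificity, then lower threshold), and attaches a DeLong-variance
normal CI.  Correlated AUCs measured on the same subjects are compared
with the paired DeLong test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort_params import LABEL_METASTASIS
from .errors import DegenerateModelError, DegenerateROCError, ValidationError


@dataclass
class LogisticModel:
    predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    odds_ratios: dict[str, float]
    or_ci: dict[str, tuple[float, float]]
    p_values: dict[str, float]
    elimination_trace: list[tuple[int, str, float]]  # (step, removed, removal p)
    converged: bool
    separation_flag: str | None = None
    or_scale: str = "unit"


def _outcome_vector(cohort: pd.DataFrame) -> np.ndarray:
    y = (cohort["label"] == LABEL_METASTASIS).to_numpy(int)
    if y.min() == y.max():
        raise ValidationError("outcome must contain both classes")
    return y


def fit_logistic_backward(
    cohort: pd.DataFrame,
    predictors: list[str],
    removal_p: float = 0.10,
    or_scale: str = "unit",
) -> LogisticModel:
    """Backward-elimination logistic regression for metastasis vs not.

    Starting from the full model, repeatedly drop the predictor with the
    largest Wald p-value while it exceeds ``removal_p``, refitting after
    each removal; an intercept-only model is a legitimate endpoint.
    ``or_scale='sd'`` rescales coefficients to per-one-SD-of-predictor.
    Perfect separation is reported as a flagged non-converged model, not
    as silently enormous coefficients.
    """
    if or_scale not in ("unit", "sd"):
        raise ValidationError("or_scale must be 'unit' or 'sd'")
    if len(predictors) < 1:
        raise ValidationError("need at least one predictor")
    y = _outcome_vector(cohort)
    if cohort[predictors].isna().any().any():
        raise ValidationError("missing values among predictors")
    current = list(predictors)
    trace: list[tuple[int, str, float]] = []
    step = 0
    while True:
        fit, flag = _fit_once(cohort, current, y)
        if flag is not None:
            return _package(fit, current, trace, cohort, or_scale,
                            converged=False, separation_flag=flag)
        if not current:
            break
        wald_p = {c: float(fit.pvalues[c]) for c in current}
        worst = max(current, key=lambda c: (wald_p[c], current.index(c)))
        if wald_p[worst] > removal_p:
            step += 1
            trace.append((step, worst, wald_p[worst]))
            current.remove(worst)
            continue
        break
    fit, flag = _fit_once(cohort, current, y)
    return _package(fit, current, trace, cohort, or_scale,
                    converged=flag is None, separation_flag=flag)


def _fit_once(cohort: pd.DataFrame, predictors: list[str], y: np.ndarray):
    x = sm.add_constant(cohort[predictors].astype(float), has_constant="add")
    x = x.rename(columns={"const": "intercept"})
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.Logit(y, x).fit(disp=0, maxiter=200)
        for w in caught:
            if "separation" in str(w.message).lower():
                return fit, _separating_predictor(cohort, predictors, y)
        if not fit.mle_retvals.get("converged", True):
            return fit, _separating_predictor(cohort, predictors, y)
    except np.linalg.LinAlgError as exc:
        # Newton's Hessian went singular: either a rank-deficient design
        # (collinearity) or diverging coefficients under separation
        design = x.to_numpy(float)
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise DegenerateModelError(
                f"singular design over {predictors}; prune collinear features first"
            ) from exc
        return None, _separating_predictor(cohort, predictors, y)
    except Exception as exc:  # statsmodels PerfectSeparationError
        if "separation" in type(exc).__name__.lower() or "separation" in str(exc).lower():
            return None, _separating_predictor(cohort, predictors, y)
        raise
    return fit, None


def _separating_predictor(cohort, predictors, y) -> str:
    """Name the predictor whose two class ranges overlap least."""
    best, best_gap = predictors[0] if predictors else "intercept", -math.inf
    for c in predictors:
        v = cohort[c].to_numpy(float)
        gap = min(v[y == 1].min() - v[y == 0].max(), v[y == 0].min() - v[y == 1].max())
        if gap > best_gap:
            best, best_gap = c, gap
    return f"perfect separation (predictor {best!r})"


def _package(fit, predictors, trace, cohort, or_scale, converged, separation_flag=None):
    if fit is None:
        return LogisticModel(
            predictors=list(predictors), coefficients={}, odds_ratios={}, or_ci={},
            p_values={}, elimination_trace=trace, converged=False,
            separation_flag=separation_flag, or_scale=or_scale,
        )
    params = fit.params
    se = fit.bse
    scale = {c: 1.0 for c in predictors}
    if or_scale == "sd":
        scale = {c: float(cohort[c].std(ddof=1)) for c in predictors}
    coefs = {name: float(params[name]) for name in params.index}
    ors, cis, ps = {}, {}, {}
    z = 1.959963984540054  # Phi^-1(0.975)
    def _exp(v: float) -> float:
        try:
            return math.exp(v)
        except OverflowError:
            return math.inf

    for c in predictors:
        b, s = coefs[c] * scale[c], float(se[c]) * scale[c]
        ors[c] = _exp(b)
        cis[c] = (_exp(b - z * s), _exp(b + z * s))
        ps[c] = float(fit.pvalues[c])
    return LogisticModel(
        predictors=list(predictors),
        coefficients=coefs,
        odds_ratios=ors,
        or_ci=cis,
        p_values=ps,
        elimination_trace=trace,
        converged=converged,
        separation_flag=separation_flag,
        or_scale=or_scale,
    )


# ---------------------------------------------------------------------------
# ROC / Youden / DeLong


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    optimal_threshold: float
    optimal_sensitivity: float
    optimal_specificity: float
    youden: float
    positive_direction: str


def _prep_marker(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if v.shape != y.shape or v.ndim != 1:
        raise ValidationError("values and labels must be matching 1D arrays")
    if y.min() == y.max():
        raise ValidationError("both classes must be present")
    return v, y


def mann_whitney_auc(values, labels, positive_direction: str = "higher") -> float:
    """AUC as the concordance probability P(X_pos > X_neg) + 0.5 P(tie)."""
    v, y = _prep_marker(values, labels)
    if positive_direction == "lower":
        v = -v
    pos, neg = v[y == 1], v[y == 0]
    ranks = _midranks(np.concatenate([pos, neg]))
    m, n = len(pos), len(neg)
    return float((ranks[:m].sum() - m * (m + 1) / 2) / (m * n))


def _midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (1-based, ties averaged)."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j < len(sx) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midranks(allv)
    r_pos = _midranks(pos)
    r_neg = _midranks(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = v10.mean()
    return v10, v01, float(auc)


def roc(values, labels, positive_direction: str = "higher") -> ROCResult:
    """Full ROC analysis of one marker.

    ``positive_direction='higher'`` means larger values indicate the
    positive (metastasis) class; thresholds classify positive at
    value >= threshold (after direction folding).
    """
    if positive_direction not in ("higher", "lower"):
        raise ValidationError("positive_direction must be 'higher' or 'lower'")
    v, y = _prep_marker(values, labels)
    w = -v if positive_direction == "lower" else v
    uniq = np.unique(w)
    if len(uniq) == 1:
        raise DegenerateROCError("constant marker values")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thr = np.concatenate([[-np.inf], mids, [np.inf]])
    pos, neg = w[y == 1], w[y == 0]
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    v10, v01, auc = _placements(pos, neg)
    m, n = len(pos), len(neg)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    z = 1.959963984540054
    half = z * math.sqrt(max(var, 0.0))
    youden = sens + spec - 1.0
    best = max(
        range(len(thr)),
        key=lambda i: (youden[i], spec[i], -thr[i] if np.isfinite(thr[i]) else math.inf),
    )
    opt_thr = thr[best] if positive_direction == "higher" else -thr[best]
    return ROCResult(
        thresholds=thr if positive_direction == "higher" else -thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        auc_ci=(max(0.0, auc - half), min(1.0, auc + half)),
        optimal_threshold=float(opt_thr),
        optimal_sensitivity=float(sens[best]),
        optimal_specificity=float(spec[best]),
        youden=float(youden[best]),
        positive_direction=positive_direction,
    )


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    difference: float
    variance: float
    z: float
    p: float


def compare_auc_delong(values_a, values_b, labels) -> AUCComparison:
    """Paired DeLong test for two markers measured on the same subjects.

    Var(A1 - A2) = S10_11/m + S01_11/n + S10_22/m + S01_22/n
    - 2 (S10_12/m + S01_12/n) from the placement-value covariances.
    """
    va, y = _prep_marker(values_a, labels)
    vb, yb = _prep_marker(values_b, labels)
    if not np.array_equal(y, yb):
        raise ValidationError("markers must share the same subjects/labels")
    v10a, v01a, auc_a = _placements(va[y == 1], va[y == 0])
    v10b, v01b, auc_b = _placements(vb[y == 1], vb[y == 0])
    m, n = int((y == 1).sum()), int((y == 0).sum())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (
        s10[0, 0] / m + s01[0, 0] / n + s10[1, 1] / m + s01[1, 1] / n
        - 2 * (s10[0, 1] / m + s01[0, 1] / n)
    )
    diff = auc_a - auc_b
    if var <= 0 or np.isclose(va, vb).all():
        return AUCComparison(auc_a, auc_b, diff, max(var, 0.0), 0.0, 1.0)
    z = diff / math.sqrt(var)
    p = 2.0 * (1.0 - _norm_cdf(abs(z)))
    return AUCComparison(auc_a, auc_b, float(diff), float(var), float(z), float(p))


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))
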