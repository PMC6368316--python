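"""Univariate statistics: group comparison, reproducibility, collinearity.

Implements the pooled (Student) independent-sample t-test from group
summaries — the variant that reproduces the published per-feature
p-values — with Welch as an option; ICC(2,1) (two-way random effects,
absolute agreement, single measure) with the F-based 95% CI for the
two-observer reproducibility analysis; and greedy Pearson-correlation
pruning with a VIF check for the multivariate candidate set.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_params import LABEL_METASTASIS, LABEL_NON_METASTASIS
from .errors import (
    DegenerateModelError,
    InsufficientSampleError,
    UndefinedICCError,
    ValidationError,
)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    variant: str
    infinite_t: bool = False


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, variant: str = "pooled"
) -> TTestResult:
    """Two-sided independent-sample t-test from group summaries.

    pooled: sp^2 = ((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2),
    t = (m1-m2)/(sp sqrt(1/n1+1/n2)), df = n1+n2-2.
    welch: Satterthwaite df.
    """
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"variant must be pooled or welch, got {variant!r}")
    if s1 < 0 or s2 < 0:
        raise ValidationError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise InsufficientSampleError("each group needs n >= 2")
    if variant == "pooled":
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        df = float(n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = math.sqrt(v1 + v2)
        if se == 0:
            df = float(n1 + n2 - 2)
        else:
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if se == 0.0:
        if m1 == m2:
            return TTestResult(t=0.0, df=df, p=1.0, variant=variant)
        t = math.inf if m1 > m2 else -math.inf
        return TTestResult(t=t, df=df, p=0.0, variant=variant, infinite_t=True)
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=df, p=float(p), variant=variant)


@dataclass
class GroupComparison:
    feature: str
    mean_metastasis: float
    sd_metastasis: float
    n_metastasis: int
    mean_non_metastasis: float
    sd_non_metastasis: float
    n_non_metastasis: int
    t: float
    df: float
    p: float
    variant: str


def _split_groups(cohort: pd.DataFrame, feature: str) -> tuple[np.ndarray, np.ndarray]:
    if feature not in cohort.columns:
        raise ValidationError(f"feature {feature!r} not in cohort")
    x1 = cohort.loc[cohort["label"] == LABEL_METASTASIS, feature].to_numpy(float)
    x2 = cohort.loc[cohort["label"] == LABEL_NON_METASTASIS, feature].to_numpy(float)
    if len(x1) < 2 or len(x2) < 2:
        raise InsufficientSampleError(
            f"both groups need >= 2 values (got {len(x1)}/{len(x2)})"
        )
    return x1, x2


def ttest_cohort(cohort: pd.DataFrame, feature: str, variant: str = "pooled") -> GroupComparison:
    """Group comparison of one feature; delegates to the summary formula."""
    x1, x2 = _split_groups(cohort, feature)
    res = ttest_from_summary(
        x1.mean(), x1.std(ddof=1), len(x1), x2.mean(), x2.std(ddof=1), len(x2), variant
    )
    return GroupComparison(
        feature=feature,
        mean_metastasis=float(x1.mean()),
        sd_metastasis=float(x1.std(ddof=1)),
        n_metastasis=len(x1),
        mean_non_metastasis=float(x2.mean()),
        sd_non_metastasis=float(x2.std(ddof=1)),
        n_non_metastasis=len(x2),
        t=res.t,
        df=res.df,
        p=res.p,
        variant=res.variant,
    )


def compare_all_features(
    cohort: pd.DataFrame, features: list[str], variant: str = "pooled"
) -> pd.DataFrame:
    """Per-feature group-comparison table (the published-table analogue)."""
    rows = [ttest_cohort(cohort, f, variant).__dict__ for f in features]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ICC

ICC_BANDS = ((0.90, "excellent"), (0.75, "good"), (0.50, "moderate"))


def icc_band(icc: float) -> str:
    for cut, name in ICC_BANDS:
        if icc >= cut:
            return name
    return "poor"


@dataclass
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    band: str
    n: int


def icc_two_observer(values1, values2, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Point estimate from the mean-squares decomposition
    (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n) with k = 2
    observers; 95% CI by the standard F-based formula with Satterthwaite
    df for the rater term.
    """
    y = np.column_stack([np.asarray(values1, float), np.asarray(values2, float)])
    n, k = y.shape
    if n < 3:
        raise InsufficientSampleError("ICC needs >= 3 subjects")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_total = ((y - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_total == 0 or denom == 0:
        raise UndefinedICCError("total variance is zero; ICC undefined")
    icc = (msr - mse) / denom

    # F-based CI (two-way random, absolute agreement, single measure)
    if mse > 0:
        fj = msc / mse
        v_num = ((k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2)
        v_den = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = v_num / v_den if v_den > 0 else (n - 1) * (k - 1)
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lower = upper = icc
    return ICCResult(
        icc=float(icc),
        ci_lower=float(min(max(lower, -1.0), 1.0)),
        ci_upper=float(min(max(upper, -1.0), 1.0)),
        band=icc_band(float(icc)),
        n=n,
    )


# ---------------------------------------------------------------------------
# multicollinearity pruning


@dataclass
class PruningReport:
    correlation: pd.DataFrame
    clusters: list[list[str]]
    retained: list[str]
    excluded: list[str]
    vif: dict[str, float]
    vif_flagged: list[str] = field(default_factory=list)


def variance_inflation_factors(cohort: pd.DataFrame, features: list[str]) -> dict[str, float]:
    """VIF_j = 1/(1 - R^2_j) regressing feature j on the others (+intercept)."""
    x = cohort[features].to_numpy(float)
    n, k = x.shape
    out: dict[str, float] = {}
    for j, name in enumerate(features):
        if k == 1:
            out[name] = 1.0
            continue
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        y = x[:, j]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        out[name] = math.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def prune_collinear(
    cohort: pd.DataFrame,
    candidates: list[str],
    r_threshold: float = 0.8,
    vif_threshold: float = 5.0,
    variant: str = "pooled",
) -> PruningReport:
    """Drop collinear candidates before multivariate modelling.

    Features connected by |Pearson r| > ``r_threshold`` form clusters
    (transitive closure); each cluster keeps the feature with the
    smallest univariate group-comparison p-value (ties: first in the
    candidate order).  VIFs are then computed over the retained set and
    features at or above ``vif_threshold`` flagged.
    """
    if len(candidates) < 2:
        raise ValidationError("need >= 2 candidate features")
    missing = [c for c in candidates if c not in cohort.columns]
    if missing:
        raise ValidationError(f"candidates absent from cohort: {missing}")
    corr = cohort[candidates].corr(method="pearson")

    # transitive clusters over the |r| > threshold graph
    parent = {c: c for c in candidates}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(candidates, 2):
        if abs(corr.loc[a, b]) > r_threshold:
            parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for c in candidates:
        groups.setdefault(find(c), []).append(c)
    clusters = [sorted(g, key=candidates.index) for g in groups.values()]
    clusters.sort(key=lambda g: candidates.index(g[0]))

    pvals = {c: ttest_cohort(cohort, c, variant).p for c in candidates}
    retained, excluded = [], []
    for cluster in clusters:
        keep = min(cluster, key=lambda c: (pvals[c], candidates.index(c)))
        retained.append(keep)
        excluded.extend(c for c in cluster if c != keep)
    if not retained:
        raise DegenerateModelError("pruning retained no features")
    vif = variance_inflation_factors(cohort, retained)
    flagged = [c for c, v in vif.items() if v >= vif_threshold]
    return PruningReport(
        correlation=corr,
        clusters=clusters,
        retained=retained,
        excluded=sorted(excluded, key=candidates.index),
        vif=vif,
        vif_flagged=flagged,
    )
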