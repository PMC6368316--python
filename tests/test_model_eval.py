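import math

import numpy as np
import pandas as pd
import pytest

from nodtex.errors import DegenerateROCError, ValidationError
from nodtex.model_eval import (
    compare_auc_delong,
    fit_logistic_backward,
    mann_whitney_auc,
    roc,
)


def _cohort(y, **features):
    df = pd.DataFrame(features)
    df["label"] = np.where(np.asarray(y) == 1, "metastasis", "non_metastasis")
    df["nodule_id"] = [f"n{i}" for i in range(len(df))]
    return df


def _brute_auc(values, labels):
    """Exhaustive concordant-pair counting with half-ties."""
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    pos, neg = v[y == 1], v[y == 0]
    c = 0.0
    for p in pos:
        for q in neg:
            c += 1.0 if p > q else (0.5 if p == q else 0.0)
    return c / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc([0.0, 0.1, 0.9, 1.0], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 0.1 < r.optimal_threshold < 0.9
        assert r.optimal_sensitivity == 1.0
        assert r.optimal_specificity == 1.0

    def test_four_point_hand_enumeration(self):
        r = roc([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.optimal_threshold == pytest.approx(2.5)

    def test_constant_marker_degenerate(self):
        with pytest.raises(DegenerateROCError):
            roc([3.0, 3.0, 3.0, 3.0], [0, 1, 0, 1])

    def test_auc_equals_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 40))
            v = np.round(rng.normal(size=n), 1)  # rounding forces ties
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            assert mann_whitney_auc(v, y) == pytest.approx(_brute_auc(v, y), abs=1e-9)
            assert roc(v, y).auc == pytest.approx(_brute_auc(v, y), abs=1e-9)

    def test_auc_matches_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        v = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        assert roc(v, y).auc == pytest.approx(sk.roc_auc_score(y, v), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        v = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:2] = [0, 1]
        a1 = roc(v, y).auc
        a2 = roc(np.exp(v), y).auc
        a3 = roc(3 * v - 7, y).auc
        assert a1 == pytest.approx(a2) == pytest.approx(a3)

    def test_lower_direction_folds(self, rng):
        v = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        assert roc(v, y, "lower").auc == pytest.approx(1.0 - roc(v, y, "higher").auc)

    def test_youden_location_binormal(self):
        """Small-cohort binormal simulation (7 vs 18): the Youden cut lies
        between the two population means in the large majority of seeds and
        always within the observed data range (midpoint thresholds can land
        outside the means for a minority of small samples)."""
        between = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            pos = r.normal(-116.5, 91.8, 7)
            neg = r.normal(-242.4, 75.7, 18)
            v = np.r_[pos, neg]
            res = roc(v, np.r_[np.ones(7), np.zeros(18)])
            assert v.min() <= res.optimal_threshold <= v.max()
            if -242.4 < res.optimal_threshold < -116.5:
                between += 1
        assert between >= 80


class TestDeLong:
    def test_identical_markers(self, rng):
        v = rng.normal(size=30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        c = compare_auc_delong(v, v.copy(), y)
        assert c.difference == 0.0
        assert c.p == 1.0

    def test_signal_vs_noise(self, rng):
        y = np.r_[np.ones(200), np.zeros(200)].astype(int)
        signal = np.r_[rng.normal(3, 1, 200), rng.normal(0, 1, 200)]
        noise = rng.normal(size=400)
        c = compare_auc_delong(signal, noise, y)
        assert c.p < 0.001
        assert c.auc_a > 0.95

    def test_antisymmetry(self, rng):
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        a = rng.normal(size=80) + y
        b = rng.normal(size=80) + 0.5 * y
        c1 = compare_auc_delong(a, b, y)
        c2 = compare_auc_delong(b, a, y)
        assert c1.difference == pytest.approx(-c2.difference)
        assert c1.z == pytest.approx(-c2.z)
        assert c1.p == pytest.approx(c2.p)

    def test_variance_close_to_bootstrap(self, rng):
        """DeLong variance of the AUC difference vs a 2000-resample bootstrap."""
        n = 250
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        shared = rng.normal(size=n)
        a = shared + 1.2 * y + rng.normal(0, 0.8, n)
        b = shared + 0.8 * y + rng.normal(0, 0.8, n)
        c = compare_auc_delong(a, b, y)
        boots = []
        for _ in range(2000):
            idx = np.r_[
                rng.choice(np.where(y == 1)[0], n // 2),
                rng.choice(np.where(y == 0)[0], n // 2),
            ]
            boots.append(
                mann_whitney_auc(a[idx], y[idx]) - mann_whitney_auc(b[idx], y[idx])
            )
        assert c.variance == pytest.approx(np.var(boots, ddof=1), rel=0.15)

    def test_mismatched_labels_rejected(self, rng):
        v = rng.normal(size=10)
        with pytest.raises(ValidationError):
            compare_auc_delong(v, v, np.ones(10, dtype=int))


class TestBackwardLogistic:
    def test_pure_noise_reduces_to_intercept(self):
        """A noise predictor is dropped in the large majority of replicates
        (its Wald p is uniform, so ~10% survive a 0.10 removal threshold)."""
        dropped = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 2000
            y = r.integers(0, 2, size=n)
            model = fit_logistic_backward(_cohort(y, junk=r.normal(size=n)), ["junk"])
            dropped += model.predictors == []
        assert dropped >= 15

    def test_generating_or_recovered(self, rng):
        """logit p = b0 + 0.0139 x: the per-HU OR e^0.0139 = 1.014 is recovered."""
        n = 10_000
        x = rng.normal(-100, 150, size=n)
        logit = 1.5 + 0.0139 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        df = _cohort(y, mean_attenuation=x)
        model = fit_logistic_backward(df, ["mean_attenuation"])
        orr = model.odds_ratios["mean_attenuation"]
        assert 1.010 <= orr <= 1.018
        lo, hi = model.or_ci["mean_attenuation"]
        assert lo <= math.exp(0.0139) <= hi

    def test_noise_dropped_signal_kept(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * x)))).astype(int)
        df = _cohort(y, signal=x, junk=rng.normal(size=n))
        model = fit_logistic_backward(df, ["signal", "junk"])
        assert model.predictors == ["signal"]
        assert any(rem == "junk" for _, rem, _ in model.elimination_trace)

    def test_or_equals_exp_coefficient(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(int)
        df = _cohort(y, f=x)
        m = fit_logistic_backward(df, ["f"], removal_p=1.0)
        assert m.odds_ratios["f"] == pytest.approx(math.exp(m.coefficients["f"]), rel=1e-9)

    def test_model_size_monotone_in_removal_p(self, rng):
        n = 500
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 * x1 + 0.1 * x2)))).astype(int)
        df = _cohort(y, a=x1, b=x2)
        full = fit_logistic_backward(df, ["a", "b"], removal_p=1.0)
        none = fit_logistic_backward(df, ["a", "b"], removal_p=1e-12)
        assert full.predictors == ["a", "b"]
        assert none.predictors == []

    def test_perfect_separation_flagged(self):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        x = np.r_[np.linspace(1, 2, 10), np.linspace(-2, -1, 10)]
        df = _cohort(y, sep=x)
        model = fit_logistic_backward(df, ["sep"])
        assert not model.converged
        assert "sep" in (model.separation_flag or "")

    def test_per_sd_scaling(self, rng):
        n = 2000
        x = rng.normal(0, 50, size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-0.02 * x))).astype(int)
        df = _cohort(y, f=x)
        unit = fit_logistic_backward(df, ["f"], removal_p=1.0, or_scale="unit")
        sd = fit_logistic_backward(df, ["f"], removal_p=1.0, or_scale="sd")
        s = df["f"].std(ddof=1)
        assert math.log(sd.odds_ratios["f"]) == pytest.approx(
            s * math.log(unit.odds_ratios["f"]), rel=1e-9
        )
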