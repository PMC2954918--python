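import warnings

import numpy as np
import pytest

import stabmi as sm
from stabmi.cohort import AnalysisConfig
from stabmi.errors import DegenerateDataError, DegeneratePredictorError
from stabmi.impute import ImputationResult
from stabmi.performance import (PerformanceReport, c_index, c_index_ci,
                                calibration_slope, mi_performance,
                                nagelkerke_r2, validate_optimism)
from stabmi.selection import LogisticModel, fit_logistic

from conftest import logistic_cohort, make_table


def _brute_c(scores, y):
    s = np.asarray(scores, float)
    y = np.asarray(y, float)
    num = tot = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            tot += 1
            if s[i] > s[j]:
                num += 1
            elif s[i] == s[j]:
                num += 0.5
    return num / tot


def test_c_index_examples():
    assert c_index([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert c_index([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
    assert c_index([0.9, 0.4, 0.4, 0.1], [1, 1, 0, 0]) == pytest.approx(0.875)


def test_c_index_equals_all_pairs_count(rng):
    for _ in range(25):
        n = int(rng.integers(10, 300))
        s = np.round(rng.random(n), 2)         # induce ties
        y = (rng.random(n) < 0.4).astype(float)
        if y.min() == y.max():
            continue
        assert c_index(s, y) == pytest.approx(_brute_c(s, y), abs=1e-12)


def test_c_index_one_class_errors():
    with pytest.raises(DegenerateDataError):
        c_index([0.1, 0.9], [1, 1])


def test_ci_contains_point_estimate_and_shrinks_with_n(rng):
    def width(n):
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        c, lo, hi = c_index_ci(x, y)
        assert lo <= c <= hi
        return hi - lo
    assert width(1000) < width(100)


def test_ci_coverage_near_nominal():
    """Binormal scores with true AUC 0.7: 95% interval covers in [92%, 98%]."""
    mu = np.sqrt(2.0) * 0.5244005127080409    # Phi(mu/sqrt(2)) = 0.7
    covered = 0
    reps = 500
    for s in range(reps):
        rng = np.random.default_rng(31000 + s)
        neg = rng.standard_normal(250)
        pos = rng.standard_normal(250) + mu
        scores = np.concatenate([neg, pos])
        y = np.concatenate([np.zeros(250), np.ones(250)])
        _, lo, hi = c_index_ci(scores, y)
        covered += lo <= 0.7 <= hi
    assert 0.92 <= covered / reps <= 0.98


def test_calibration_slope_identity_and_halving(rng):
    t = logistic_cohort(rng, 400, {"a": 0.8, "b": 0.4})
    m = fit_logistic(t, "y", ["a", "b"])
    lp = m.linear_predictor(t)
    y = t.values("y")
    assert calibration_slope(lp, y) == pytest.approx(1.0, abs=1e-6)
    assert calibration_slope(2 * lp, y) == pytest.approx(0.5, abs=1e-6)


def test_calibration_slope_constant_lp_errors():
    with pytest.raises(DegeneratePredictorError):
        calibration_slope(np.ones(20), np.tile([0.0, 1.0], 10))


def test_overfitted_model_shrinks_on_fresh_data():
    slopes = []
    for s in range(50):
        rng = np.random.default_rng(60000 + s)
        betas = {f"x{i}": 0.0 for i in range(15)}
        train = logistic_cohort(rng, 100, betas)
        test = logistic_cohort(rng, 500, betas)
        m = fit_logistic(train, "y", list(betas))
        if not m.converged:
            continue
        lp = m.linear_predictor(test)
        try:
            slopes.append(calibration_slope(lp, test.values("y")))
        except DegeneratePredictorError:
            continue
    assert float(np.mean(slopes)) < 1.0


def _model_with_ll(ll0, ll1, n):
    return LogisticModel(("x",), ("(intercept)", "x"), np.zeros(2),
                         np.eye(2), ll1, ll0, n, True)


def test_nagelkerke_hand_worked_value():
    m = _model_with_ll(-2.7726, -1.3863, 4)
    cs = 1 - np.exp(2 * (-2.7726 + 1.3863) / 4)
    assert cs == pytest.approx(0.5, abs=1e-4)
    assert nagelkerke_r2(m) == pytest.approx(0.6667, abs=1e-3)


def test_nagelkerke_zero_when_no_improvement_and_monotone():
    assert nagelkerke_r2(_model_with_ll(-5.0, -5.0, 10)) == 0.0
    vals = [nagelkerke_r2(_model_with_ll(-5.0, ll1, 10))
            for ll1 in (-4.0, -3.0, -1.0, -0.1)]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_corrected_c_is_apparent_minus_optimism(rng):
    t = logistic_cohort(rng, 300, {"a": 0.6, "b": 0.3})
    cfg = AnalysisConfig(b_validation=50)
    rep = validate_optimism(t, "y", ("a", "b"), cfg, seed=1)
    assert rep.corrected_c == pytest.approx(rep.apparent_c - rep.optimism)
    assert rep.c_ci_low <= rep.apparent_c <= rep.c_ci_high
    assert rep.calibration_slope == pytest.approx(1.0, abs=1e-6)


def test_selected_models_show_positive_optimism_on_average():
    opts = []
    for s in range(10):
        rng = np.random.default_rng(71000 + s)
        betas = {f"x{i}": 0.0 for i in range(8)}
        t = logistic_cohort(rng, 120, betas)
        rep = validate_optimism(t, "y", tuple(betas), AnalysisConfig(b_validation=40),
                                seed=s)
        opts.append(rep.optimism)
    assert float(np.mean(opts)) > 0.0


def test_intercept_only_validation_is_chance_level(rng):
    t = logistic_cohort(rng, 100, {"a": 0.0})
    rep = validate_optimism(t, "y", (), AnalysisConfig(b_validation=20), seed=0)
    assert rep.apparent_c == 0.5 and rep.optimism == 0.0 and rep.corrected_c == 0.5


def test_mi_performance_on_identical_datasets_matches_single(rng):
    t = logistic_cohort(rng, 300, {"a": 0.7})
    cfg = AnalysisConfig(b_validation=60)
    imps = ImputationResult([t, t, t], 3, 1, 0, {})
    pooled = mi_performance(imps, "y", ("a",), cfg, seed=5)
    single = validate_optimism(t, "y", ("a",), cfg, seed=5)
    assert pooled.apparent_c == pytest.approx(single.apparent_c)
    assert pooled.calibration_slope == pytest.approx(single.calibration_slope)
    assert pooled.r2_nagelkerke == pytest.approx(single.r2_nagelkerke)
    # optimism is a bootstrap mean; different resample streams agree loosely
    assert pooled.optimism == pytest.approx(single.optimism, abs=0.03)
    assert pooled.corrected_c == pytest.approx(pooled.apparent_c - pooled.optimism)


def test_mi_corrected_c_tracks_holdout_performance():
    """Optimism-corrected c on the derivation cohort should approximate the
    c measured on a large independent cohort from the same process."""
    diffs = []
    for s in range(3):
        table, _ = sm.generate(sm.recovery_preset(seed=82000 + s))
        big, _ = sm.generate(sm.recovery_preset(seed=90000 + s, n=5000,
                                                mar_rate=0.0))
        imps = sm.impute(table, m=5, n_iter=5, seed=s)
        comp = tuple(f"true_{i}" for i in range(1, 5))
        pooled = mi_performance(imps, "persistent", comp,
                                AnalysisConfig(b_validation=60), seed=s)
        ref = fit_logistic(imps.completed[0], "persistent", list(comp))
        risks = ref.predicted_risk(big)
        c_hold = c_index(risks, big.values("persistent"))
        diffs.append(abs(pooled.corrected_c - c_hold))
    assert float(np.mean(diffs)) < 0.05
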