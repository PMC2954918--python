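import warnings

import numpy as np
import pytest
import statsmodels.api as sm_api
from scipy import stats

import stabmi as sm
from stabmi.cohort import AnalysisConfig, VariableSpec
from stabmi.errors import ConfigurationError, DegenerateDataError
from stabmi.impute import ImputationResult
from stabmi.selection import (InclusionTable, LogisticModel, ModelComposition,
                              backward_eliminate, fit_logistic, lrt_drop_one,
                              mi_select, pool_rubin, pooled_lrt)

from conftest import logistic_cohort, make_table


# -- fit_logistic -----------------------------------------------------------

def test_intercept_only_fit_is_logit_of_event_fraction(rng):
    y = (rng.random(80) < 0.3).astype(float)
    t = make_table({"y": y})
    m = fit_logistic(t, "y", [])
    pbar = y.mean()
    assert m.intercept == pytest.approx(np.log(pbar / (1 - pbar)))
    assert m.log_likelihood == pytest.approx(m.null_log_likelihood)


def test_balanced_toy_has_zero_coefficients():
    t = make_table({"y": [0.0, 0.0, 1.0, 1.0], "x": [0.0, 1.0, 0.0, 1.0]})
    m = fit_logistic(t, "y", ["x"])
    assert m.intercept == pytest.approx(0.0, abs=1e-8)
    assert m.coefficients["x"] == pytest.approx(0.0, abs=1e-8)


def test_estimate_recovers_true_log_odds(rng):
    t = logistic_cohort(rng, 500, {"x": 0.7})
    m = fit_logistic(t, "y", ["x"])
    se = np.sqrt(m.cov_params[1, 1])
    assert abs(m.coefficients["x"] - 0.7) < 3 * se


def test_matches_statsmodels_on_random_instances(rng):
    """Independent-oracle check of the ML engine: coefficients and
    log-likelihood agree with statsmodels on random problems."""
    for _ in range(10):
        n = int(rng.integers(60, 300))
        k = int(rng.integers(1, 5))
        betas = {f"x{i}": float(rng.normal(0, 0.8)) for i in range(k)}
        t = logistic_cohort(rng, n, betas)
        mine = fit_logistic(t, "y", list(betas))
        X = sm_api.add_constant(np.column_stack([t.values(v) for v in betas]))
        ref = sm_api.Logit(t.values("y"), X).fit(disp=0)
        assert np.allclose(mine.params, ref.params, atol=1e-6)
        assert mine.log_likelihood == pytest.approx(ref.llf, abs=1e-8)


def test_one_class_outcome_errors():
    t = make_table({"y": np.ones(10), "x": np.arange(10.0)})
    with pytest.raises(DegenerateDataError):
        fit_logistic(t, "y", ["x"])


def test_separation_sets_converged_false():
    y = np.tile([0.0, 1.0], 20)
    t = make_table({"y": y, "x": y * 2 - 1})
    m = fit_logistic(t, "y", ["x"])
    assert not m.converged


# -- backward elimination ----------------------------------------------------

def test_alpha_one_keeps_full_model(rng):
    t = logistic_cohort(rng, 300, {"a": 0.0, "b": 0.0, "c": 0.5})
    res = backward_eliminate(t, "y", ["a", "b", "c"], alpha=0.999999)
    assert set(res.model.predictors) == {"a", "b", "c"}


def test_tiny_alpha_leaves_intercept_only(rng):
    t = logistic_cohort(rng, 300, {"a": 0.0, "b": 0.0})
    res = backward_eliminate(t, "y", ["a", "b"], alpha=1e-12)
    assert res.model.predictors == ()
    assert len(res.removal_trace) == 2


def test_strong_predictor_survives():
    kept = 0
    for s in range(50):
        rng = np.random.default_rng(8800 + s)
        t = logistic_cohort(rng, 500, {"x": 1.0})
        res = backward_eliminate(t, "y", ["x"], alpha=0.157)
        kept += res.model.predictors == ("x",)
    assert kept >= 50 * 0.99


def test_retained_set_is_monotone_in_alpha(rng):
    t = logistic_cohort(rng, 200, {"a": 0.4, "b": 0.2, "c": 0.0, "d": 0.0})
    big = set(backward_eliminate(t, "y", list("abcd"), alpha=0.5).model.predictors)
    small = set(backward_eliminate(t, "y", list("abcd"), alpha=0.05).model.predictors)
    assert small <= big


def test_result_invariant_to_start_ordering(rng):
    t = logistic_cohort(rng, 150, {"a": 0.3, "b": 0.0, "c": 0.3})
    r1 = backward_eliminate(t, "y", ["a", "b", "c"], alpha=0.157)
    r2 = backward_eliminate(t, "y", ["c", "a", "b"], alpha=0.157)
    assert r1.model.predictors == r2.model.predictors
    assert r1.removal_trace == r2.removal_trace


def test_drop_one_lrt_is_nonnegative(rng):
    t = logistic_cohort(rng, 120, {"a": 0.5, "b": 0.0})
    full = fit_logistic(t, "y", ["a", "b"])
    for name in ("a", "b"):
        stat, p = lrt_drop_one(t, "y", full, name)
        assert stat >= 0.0 and 0.0 <= p <= 1.0


# -- pooled LRT and MI selection ---------------------------------------------

def test_pooled_lrt_m1_equals_plain_chi2():
    assert pooled_lrt([4.0], 1) == pytest.approx(float(stats.chi2.sf(4.0, 1)))


def test_inclusion_fraction_threshold_semantics():
    cands = ["a", "b", "c"]
    comps = [ModelComposition(c) for c in
             (("a", "b"), ("a",), ("a", "b"), ("c",), ("a",))]
    table = InclusionTable.from_models(comps, cands)
    fr = table.fractions
    assert fr["a"] == pytest.approx(0.8)
    assert fr["b"] == pytest.approx(0.4)    # 2 of 5 -> qualifies at 40%
    assert fr["c"] == pytest.approx(0.2)    # 1 of 5 -> excluded
    assert set(table.qualified(0.40)) == {"a", "b"}


def test_mi_select_on_m1_degenerates_to_backward(rng):
    t = logistic_cohort(rng, 400, {"a": 0.8, "b": 0.0, "c": 0.6})
    imps = ImputationResult([t], 1, 1, 0, {})
    cfg = AnalysisConfig(m_imputations=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = mi_select(imps, "y", ["a", "b", "c"], cfg)
        uni = sm.univariable_screen(t, "y", ["a", "b", "c"], cfg.alpha_univariable)
        ref = backward_eliminate(t, "y", list(uni.retained), cfg.alpha_backward)
    assert tuple(sel.confirmed) == ref.model.predictors


def test_mi_select_recovers_structure_under_missingness():
    """Four true effects plus noise with ~10% MAR missingness: the
    inclusion-fraction + pooled-LRT chain should find the true set."""
    hits = 0
    for s in range(5):
        table, _ = sm.generate(sm.recovery_preset(seed=6100 + s))
        imps = sm.impute(table, m=5, n_iter=10, seed=s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = mi_select(imps, "persistent", table.candidates(),
                            AnalysisConfig())
        hits += {f"true_{i}" for i in range(1, 5)} <= set(sel.confirmed)
    assert hits >= 4


# -- Rubin's rules -----------------------------------------------------------

def _toy_model(params, var):
    k = len(params)
    return LogisticModel(("x",) * 0 if k == 1 else tuple(f"x{i}" for i in range(k - 1)),
                         tuple(["(intercept)"] + [f"x{i}" for i in range(k - 1)]),
                         np.asarray(params, float), np.diag(var),
                         -1.0, -2.0, 10, True)


def test_pool_identical_models_has_zero_between_variance():
    m = _toy_model([0.1, 0.4], [0.02, 0.01])
    pooled = pool_rubin([m, m, m])
    assert np.allclose(pooled.estimates, [0.1, 0.4])
    assert np.allclose(pooled.between_variance, 0.0)
    assert np.allclose(pooled.total_variance, [0.02, 0.01])


def test_pool_two_models_hand_arithmetic():
    m1 = _toy_model([0.0, 0.4], [0.0, 0.01])
    m2 = _toy_model([0.0, 0.6], [0.0, 0.01])
    pooled = pool_rubin([m1, m2])
    assert pooled.estimates[1] == pytest.approx(0.5)
    # B = var([0.4, 0.6]) = 0.02; total = 0.01 + 1.5 * 0.02 = 0.04
    assert pooled.total_variance[1] == pytest.approx(0.04)


def test_pool_mismatched_compositions_errors():
    m1 = _toy_model([0.0, 0.4], [0.0, 0.01])
    m2 = _toy_model([0.0], [0.01])
    with pytest.raises(ConfigurationError):
        pool_rubin([m1, m2])
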