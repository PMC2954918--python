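import warnings

import numpy as np
import pytest

import stabmi as sm
from stabmi.cohort import VariableSpec
from stabmi.errors import (ConfigurationError, DegenerateDataError,
                           DegeneratePredictorError, UndefinedChangeError)
from stabmi.screening import (collinearity_filter, dichotomize_outcome,
                              events_per_variable, linearity_check,
                              optimal_cutoff, relative_change,
                              univariable_screen)

from conftest import logistic_cohort, make_table


# -- relative change and dichotomisation -----------------------------------

@pytest.mark.parametrize("baseline,followup,expected", [
    (60, 25, (60 - 25) / 60),
    (60, 60, 0.0),
    (60, 90, -0.5),
])
def test_relative_change_arithmetic(baseline, followup, expected):
    assert relative_change(baseline, followup) == pytest.approx(expected)


def test_relative_change_zero_baseline():
    with pytest.raises(UndefinedChangeError):
        relative_change(0, 10)
    with pytest.warns(UserWarning):
        out = relative_change([0.0, 60.0], [10.0, 30.0])
    assert np.isnan(out[0]) and out[1] == pytest.approx(0.5)


@pytest.mark.parametrize("change,expected", [
    ((60 - 25) / 60, 0.0),   # improved 58% -> not persistent
    (0.5, 0.0),              # exactly 50% improvement counts as improved
    (-0.2, 1.0),             # worsening is persistent
])
def test_dichotomize_persistence_is_strictly_below_cutoff(change, expected):
    assert dichotomize_outcome(change, 0.5) == expected


# -- optimal cutoff ---------------------------------------------------------

def _brute_force_cutoff(changes, recovered):
    """Exhaustive misclassification minimum over a dense threshold grid."""
    changes = np.asarray(changes, float)
    recovered = np.asarray(recovered, float)
    grid = np.unique(np.concatenate([changes, changes - 1e-9, changes + 1e-9]))
    best = None
    for t in grid:
        pred = (changes >= t).astype(float)
        mis = int(np.sum(pred != recovered))
        if best is None or mis < best:
            best = mis
    return best


def test_cutoff_separable_example():
    res = optimal_cutoff([0.8, 0.7, 0.6, 0.2, 0.1], [1, 1, 1, 0, 0])
    assert res.misclassification == 0
    assert 0.2 < res.threshold <= 0.6
    # tie-break: candidate nearest 0.5 among zero-misclassification thresholds
    assert res.threshold == pytest.approx(0.4)
    assert res.sensitivity == 1.0 and res.specificity == 1.0


def test_cutoff_interleaved_classes():
    # classes interleave along the change axis: best split still errs once
    res = optimal_cutoff([0.1, 0.2, 0.3, 0.4], [0, 1, 0, 1])
    assert res.misclassification == 1


def test_cutoff_matches_brute_force_on_random_instances(rng):
    for _ in range(30):
        n = int(rng.integers(5, 200))
        changes = rng.normal(0.4, 0.3, n)
        recovered = (changes + rng.normal(0, 0.3, n) > 0.4).astype(float)
        if np.unique(recovered).size < 2:
            continue
        res = optimal_cutoff(changes, recovered)
        assert res.misclassification == _brute_force_cutoff(changes, recovered)


def test_cutoff_one_class_criterion_errors():
    with pytest.raises(DegenerateDataError):
        optimal_cutoff([0.1, 0.2, 0.3], [1, 1, 1])


# -- linearity check --------------------------------------------------------

def test_linearity_check_keeps_truly_linear_relation():
    # under a truly linear log-odds relation the augmentation test rejects
    # at its type-I rate alpha = 0.157, so ~84% of runs keep the linear term
    keep = 0
    for s in range(50):
        rng = np.random.default_rng(500 + s)
        x = rng.standard_normal(500)
        y = (rng.random(500) < 1 / (1 + np.exp(-x))).astype(float)
        keep += linearity_check(x, y, 3).recommendation == "keep linear"
    assert keep >= 35


def test_linearity_check_flags_step_function():
    cat = 0
    for s in range(50):
        rng = np.random.default_rng(900 + s)
        x = rng.standard_normal(500)
        lp = np.where(x > 0.5, 1.5, -1.5)
        y = (rng.random(500) < 1 / (1 + np.exp(-lp))).astype(float)
        cat += linearity_check(x, y, 3).recommendation == "categorize"
    assert cat >= 45


def test_linearity_check_constant_predictor_errors():
    with pytest.raises(DegeneratePredictorError):
        linearity_check(np.ones(100), np.tile([0.0, 1.0], 50), 3)


# -- collinearity filter ----------------------------------------------------

def _prio_table(cols, priorities, mask=None):
    specs = [VariableSpec(n, "candidate", clinical_priority=p)
             for n, p in priorities.items()]
    return make_table(cols, specs=specs, mask=mask)


def test_independent_columns_nothing_dropped(rng):
    t = _prio_table({"x1": rng.standard_normal(1000),
                     "x2": rng.standard_normal(1000)}, {"x1": 1, "x2": 2})
    res = collinearity_filter(t, ["x1", "x2"], 0.5)
    assert res.dropped == ()
    assert set(res.retained) == {"x1", "x2"}


def test_perfect_duplicate_drops_lower_priority(rng):
    x = rng.standard_normal(100)
    t = _prio_table({"x1": x, "x2": x.copy()}, {"x1": 1, "x2": 2})
    res = collinearity_filter(t, ["x1", "x2"], 0.5)
    assert res.retained == ("x1",)
    (dropped, kept, r), = res.dropped
    assert (dropped, kept) == ("x2", "x1") and r == pytest.approx(1.0)


def test_three_way_correlation_keeps_only_best_priority(rng):
    z = rng.standard_normal(2000)
    cols = {f"x{i}": 0.9 * z + np.sqrt(1 - 0.81) * rng.standard_normal(2000)
            for i in (1, 2, 3)}
    t = _prio_table(cols, {"x1": 1, "x2": 2, "x3": 3})
    res = collinearity_filter(t, ["x1", "x2", "x3"], 0.5)
    assert res.retained == ("x1",)
    assert {d for d, _, _ in res.dropped} == {"x2", "x3"}


def test_collinearity_filter_invariant_to_candidate_order(rng):
    z = rng.standard_normal(500)
    cols = {"a": z + 0.3 * rng.standard_normal(500),
            "b": z + 0.3 * rng.standard_normal(500),
            "c": rng.standard_normal(500)}
    t = _prio_table(cols, {"a": 2, "b": 1, "c": 3})
    r1 = collinearity_filter(t, ["a", "b", "c"], 0.5)
    r2 = collinearity_filter(t, ["c", "b", "a"], 0.5)
    assert r1.retained == r2.retained and r1.dropped == r2.dropped


def test_missing_priority_is_a_configuration_error(rng):
    x = rng.standard_normal(50)
    specs = [VariableSpec("x1", "candidate", clinical_priority=1),
             VariableSpec("x2", "candidate")]
    t = make_table({"x1": x, "x2": x.copy()}, specs=specs)
    with pytest.raises(ConfigurationError):
        collinearity_filter(t, ["x1", "x2"], 0.5)


# -- univariable screen ------------------------------------------------------

def test_strong_predictor_is_retained():
    kept = 0
    for s in range(50):
        rng = np.random.default_rng(7000 + s)
        t = logistic_cohort(rng, 500, {"x": 1.0})
        res = univariable_screen(t, "y", ["x"], 0.157)
        kept += "x" in res.retained
    assert kept >= 50 * 0.99


def test_alpha_one_retains_everything(rng):
    t = logistic_cohort(rng, 200, {"x1": 0.0, "x2": 0.0})
    res = univariable_screen(t, "y", ["x1", "x2"], alpha=0.9999)
    assert set(res.retained) == {"x1", "x2"}


def test_separated_candidate_retained_with_warning():
    y = np.tile([0.0, 1.0], 25)
    t = make_table({"y": y, "x": y * 2 - 1})
    with pytest.warns(UserWarning, match="separation"):
        res = univariable_screen(t, "y", ["x"], 0.157)
    assert res.p_values["x"] == 0.0 and "x" in res.retained


# -- events per variable -----------------------------------------------------

def test_epv_uses_minority_class():
    y = np.concatenate([np.ones(204), np.zeros(313)])
    t = make_table({"y": y})
    assert events_per_variable(t, "y", 12) == pytest.approx(17.0)


def test_epv_boundary_warns():
    y = np.concatenate([np.ones(100), np.zeros(150)])
    t = make_table({"y": y})
    with pytest.warns(UserWarning, match="underpowered"):
        assert events_per_variable(t, "y", 10) == pytest.approx(10.0)
    with pytest.warns(UserWarning):
        assert events_per_variable(t, "y", 100) == pytest.approx(1.0)


def test_epv_zero_events_errors():
    t = make_table({"y": np.ones(20)})
    with pytest.raises(DegenerateDataError):
        events_per_variable(t, "y", 5)
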