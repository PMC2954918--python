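"""Model performance: discrimination, calibration, explained variance, and
bootstrap optimism-corrected internal validation.

Discrimination is the c-index (for a binary outcome, the area under the ROC
curve): the probability that a randomly chosen event subject receives a
higher predicted risk than a randomly chosen non-event subject, with tied
scores credited 0.5.  Calibration is summarised by the calibration slope —
the coefficient from refitting the outcome on the model's linear predictor;
well-calibrated models have slope 1.  Explained variance is Nagelkerke's R²,
the Cox–Snell R² rescaled by its attainable maximum.

Internal validation follows the bootstrap optimism recipe: refit the model
composition in each bootstrap resample, measure its performance both on the
resample and on the original data, and average the difference.  The
corrected index is the apparent index minus this optimism estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import AnalysisConfig, CohortTable
from .errors import (ConfigurationError, DegenerateDataError,
                     DegeneratePredictorError, ValidationError)
from ._logit import fit_irls, null_fit
from .impute import ImputationResult
from .selection import LogisticModel, ModelComposition, fit_logistic


# -- discrimination --------------------------------------------------------

def c_index(scores, outcomes) -> float:
    """Concordance of predicted scores with a binary outcome.

    Over all event/non-event pairs: concordant = 1, tied score = 0.5,
    discordant = 0.  Computed from midranks, which is exactly the all-pairs
    count.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError("both outcome classes are required for the c-index")
    ranks = stats.rankdata(s)
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def _placements(scores, outcomes):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    # V10[i]: fraction of non-events scored below event i (ties 0.5)
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / neg.size
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size
                    for q in neg])
    return v10, v01


def c_index_ci(scores, outcomes, level: float = 0.95):
    """Confidence interval for the c-index from the paired-placement
    (DeLong-type) variance, truncated to [0, 1].

    Returns (c, low, high).
    """
    c = c_index(scores, outcomes)
    v10, v01 = _placements(scores, outcomes)
    var = 0.0
    if v10.size > 1:
        var += np.var(v10, ddof=1) / v10.size
    if v01.size > 1:
        var += np.var(v01, ddof=1) / v01.size
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return c, float(max(0.0, c - half)), float(min(1.0, c + half))


# -- calibration and explained variance ------------------------------------

def calibration_slope(linear_predictors, outcomes) -> float:
    """Slope from a logistic refit of the outcome on the linear predictor
    (free intercept).  Equals 1 on a converged model's own derivation data;
    below 1 signals overfitting (predictions too extreme)."""
    lp = np.asarray(linear_predictors, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if np.unique(y).size < 2:
        raise DegenerateDataError("both outcome classes are required")
    if np.ptp(lp) == 0:
        raise DegeneratePredictorError("constant linear predictor")
    X = np.column_stack([np.ones(lp.size), lp])
    beta, _, _, conv = fit_irls(X, y)
    return float(beta[1])


def nagelkerke_r2(model: LogisticModel) -> float:
    """Nagelkerke's R²: Cox–Snell R² divided by its attainable maximum."""
    if model.n == 0:
        raise ConfigurationError("model has no observations")
    cs = 1.0 - np.exp(2.0 * (model.null_log_likelihood - model.log_likelihood)
                      / model.n)
    cs_max = 1.0 - np.exp(2.0 * model.null_log_likelihood / model.n)
    return float(cs / cs_max) if cs_max > 0 else 0.0


# -- reports ---------------------------------------------------------------

@dataclass(frozen=True)
class PerformanceReport:
    """Apparent and optimism-corrected performance of one model composition."""

    apparent_c: float
    c_ci_low: float
    c_ci_high: float
    calibration_slope: float
    r2_nagelkerke: float
    optimism: float
    corrected_c: float
    slope_optimism: float = float("nan")
    r2_optimism: float = float("nan")
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "apparent_c": self.apparent_c,
            "c_ci": [self.c_ci_low, self.c_ci_high],
            "calibration_slope": self.calibration_slope,
            "r2_nagelkerke": self.r2_nagelkerke,
            "optimism": self.optimism,
            "corrected_c": self.corrected_c,
        }


def _apparent(data: CohortTable, outcome: str, composition) -> tuple:
    model = fit_logistic(data, outcome, list(composition))
    y = data.values(outcome)
    if composition:
        lp = model.linear_predictor(data)
        risks = 1.0 / (1.0 + np.exp(-lp))
        c, lo, hi = c_index_ci(risks, y)
        slope = calibration_slope(lp, y)
    else:
        # intercept-only: every pair tied
        c, lo, hi = 0.5, 0.5, 0.5
        slope = float("nan")
    return model, c, lo, hi, slope, nagelkerke_r2(model)


def validate_optimism(data: CohortTable, outcome: str,
                      composition, config: AnalysisConfig,
                      seed: int = 0) -> PerformanceReport:
    """Bootstrap internal validation of a fixed model composition.

    In each of ``config.b_validation`` bootstrap resamples the composition's
    coefficients are re-estimated; the drop from bootstrap-sample performance
    to original-data performance, averaged over converged replicates, is the
    optimism.  corrected c = apparent c − optimism.
    """
    composition = ModelComposition(composition)
    model, app_c, lo, hi, app_slope, app_r2 = _apparent(data, outcome, composition)
    if not composition:
        return PerformanceReport(app_c, lo, hi, app_slope, app_r2, 0.0, app_c)
    y = data.values(outcome)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = data.n
    opt_c, opt_slope, opt_r2 = [], [], []
    failed = 0
    _, ll0_orig = null_fit(y)
    for _ in range(config.b_validation):
        idx = rng.integers(0, n, n)
        boot = data.take_rows(idx)
        yb = boot.values(outcome)
        if np.unique(yb).size < 2:
            failed += 1
            continue
        bmod = fit_logistic(boot, outcome, list(composition))
        if not bmod.converged:
            failed += 1
            continue
        risks_b = bmod.predicted_risk(boot)
        risks_o = bmod.predicted_risk(data)
        opt_c.append(c_index(risks_b, yb) - c_index(risks_o, y))
        # slope on the bootstrap sample of its own fit is 1 by the ML score
        # identity; optimism is therefore 1 − slope on the original data
        lp_o = bmod.linear_predictor(data)
        try:
            opt_slope.append(1.0 - calibration_slope(lp_o, y))
        except DegeneratePredictorError:
            pass
        ll_o = bmod.loglik_on(data, outcome)
        r2_o_num = 1.0 - np.exp(2.0 * (ll0_orig - ll_o) / n)
        r2_o = r2_o_num / (1.0 - np.exp(2.0 * ll0_orig / n))
        opt_r2.append(nagelkerke_r2(bmod) - r2_o)
    if failed > 0.2 * config.b_validation:
        raise ValidationError(
            f"{failed}/{config.b_validation} validation replicates failed")
    optimism = float(np.mean(opt_c)) if opt_c else 0.0
    return PerformanceReport(
        app_c, lo, hi, app_slope, app_r2,
        optimism, app_c - optimism,
        float(np.mean(opt_slope)) if opt_slope else float("nan"),
        float(np.mean(opt_r2)) if opt_r2 else float("nan"),
        failed)


def mi_performance(imps: ImputationResult, outcome: str, composition,
                   config: AnalysisConfig, seed: int = 0) -> PerformanceReport:
    """Optimism-corrected performance pooled over multiply-imputed datasets.

    Each completed dataset is validated independently; point metrics pool as
    arithmetic means, and the c-index CI pools DeLong within-variance with
    between-imputation variance (Rubin's rules on the c scale).
    """
    m = imps.m
    seeds = np.random.SeedSequence(seed).spawn(m)
    reports = []
    for t, ss in zip(imps.completed, seeds):
        reports.append(validate_optimism(
            t, outcome, composition, config,
            seed=int(ss.generate_state(1)[0] % (2 ** 31))))
    app = float(np.mean([r.apparent_c for r in reports]))
    slope = float(np.mean([r.calibration_slope for r in reports]))
    r2 = float(np.mean([r.r2_nagelkerke for r in reports]))
    opt = float(np.mean([r.optimism for r in reports]))
    # Rubin's rules on the c scale for the pooled CI
    within = np.mean([((r.c_ci_high - r.c_ci_low) / (2 * stats.norm.ppf(0.975))) ** 2
                      for r in reports])
    between = np.var([r.apparent_c for r in reports], ddof=1) if m > 1 else 0.0
    total_sd = np.sqrt(within + (1 + 1 / m) * between)
    z = stats.norm.ppf(0.975)
    return PerformanceReport(
        app, float(max(0.0, app - z * total_sd)), float(min(1.0, app + z * total_sd)),
        slope, r2, opt, app - opt,
        float(np.mean([r.slope_optimism for r in reports])),
        float(np.mean([r.r2_optimism for r in reports])),
        sum(r.n_failed for r in reports))
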