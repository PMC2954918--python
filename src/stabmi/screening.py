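"""Preprocessing chain for prognostic-model development.

Covers outcome construction (relative change from baseline, dichotomised at
a cutoff chosen to minimise misclassification against an external recovery
criterion), a linearity check for continuous predictors, a clinical-priority
collinearity filter, the univariable pre-selection at alpha = 0.157, and the
events-per-variable power check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._logit import fit_irls, null_fit
from .cohort import CohortTable, VariableSpec
from .errors import (ConfigurationError, DegenerateDataError,
                     DegeneratePredictorError, UndefinedChangeError)
from .selection import build_design


# -- outcome construction --------------------------------------------------

def relative_change(baseline, followup):
    """Fractional improvement from baseline: (baseline - followup)/baseline.

    Positive values mean improvement (score decreased).  A zero baseline
    makes the relative change undefined: scalars raise, array entries are
    flagged with NaN and a warning so the subject is visible, not dropped.
    """
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape == ():
        if b == 0:
            raise UndefinedChangeError("relative change undefined at baseline 0")
        return float((b - f) / b)
    zero = b == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} subject(s) have baseline 0; "
                      "relative change flagged as NaN", stacklevel=2)
    out = np.where(zero, np.nan, (b - f) / np.where(zero, np.nan, b))
    return out


def dichotomize_outcome(change, cutoff: float = 0.5):
    """Persistence indicator: 1 when improvement is strictly below cutoff.

    A subject improving less than the cutoff fraction (default 50%) is
    denoted as having a persistent problem.  NaN change propagates.
    """
    if not (0 < cutoff <= 1):
        raise ConfigurationError("cutoff must lie in (0, 1]")
    c = np.asarray(change, dtype=float)
    out = np.where(np.isnan(c), np.nan, (c < cutoff).astype(float))
    return float(out) if c.shape == () else out


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    misclassification: int
    sensitivity: float
    specificity: float


def optimal_cutoff(changes, recovered) -> CutoffResult:
    """ROC-style cutoff search: the change-score threshold with the lowest
    overall misclassification against the external recovery criterion.

    A subject is predicted recovered when change >= threshold.  Every
    distinct observed change value plus the midpoints between consecutive
    distinct values are evaluated; ties in misclassification are broken
    toward the threshold nearest 0.5.
    """
    c = np.asarray(changes, dtype=float)
    r = np.asarray(recovered, dtype=float)
    if c.size != r.size or c.size < 2:
        raise ConfigurationError("changes and recovered must be equal length >= 2")
    if np.unique(r).size < 2:
        raise DegenerateDataError("recovery criterion has only one class")
    distinct = np.unique(c)
    cands = [distinct]
    if distinct.size > 1:
        cands.append((distinct[:-1] + distinct[1:]) / 2.0)
    thresholds = np.unique(np.concatenate(cands))
    n_pos = int(r.sum())
    n_neg = int(r.size - n_pos)
    best = None
    for t in thresholds:
        pred = (c >= t).astype(float)
        fp = int(np.sum((pred == 1) & (r == 0)))
        fn = int(np.sum((pred == 0) & (r == 1)))
        mis = fp + fn
        key = (mis, abs(t - 0.5))
        if best is None or key < best[0]:
            tp = n_pos - fn
            tn = n_neg - fp
            best = (key, CutoffResult(float(t), mis, tp / n_pos, tn / n_neg))
    return best[1]


# -- linearity -------------------------------------------------------------

@dataclass(frozen=True)
class LinearityResult:
    recommendation: str                 # 'keep linear' or 'categorize'
    p_value: float
    cut_points: tuple[float, ...]       # quantile boundaries if categorizing


def linearity_check(x, y, n_groups: int = 3, alpha: float = 0.157) -> LinearityResult:
    """Check whether a continuous predictor's log-odds relation is linear.

    Fits the logistic model with a linear term and the augmented model that
    adds quantile-group indicators (tertiles for 3 groups, median split for
    2); a significant likelihood-ratio improvement of the augmentation means
    the linear shape is inadequate and the variable should be categorised at
    the quantile cut points.
    """
    if n_groups not in (2, 3):
        raise ConfigurationError("n_groups must be 2 or 3")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < n_groups:
        raise DegeneratePredictorError("predictor has too few distinct values")
    qs = np.quantile(x, np.linspace(0, 1, n_groups + 1)[1:-1])
    groups = np.digitize(x, qs)
    n = x.size
    X_lin = np.column_stack([np.ones(n), x])
    dummies = [(groups == g).astype(float) for g in range(1, n_groups)]
    X_aug = np.column_stack([X_lin] + dummies)
    _, ll_lin, _, c1 = fit_irls(X_lin, y)
    _, ll_aug, _, c2 = fit_irls(X_aug, y)
    df = n_groups - 1
    stat = max(0.0, 2.0 * (ll_aug - ll_lin))
    p = float(stats.chi2.sf(stat, df))
    if p <= alpha:
        return LinearityResult("categorize", p, tuple(float(q) for q in qs))
    return LinearityResult("keep linear", p, tuple(float(q) for q in qs))


# -- collinearity ----------------------------------------------------------

@dataclass(frozen=True)
class CollinearityResult:
    retained: tuple[str, ...]
    dropped: tuple[tuple[str, str, float], ...]   # (dropped, kept, r)


def collinearity_filter(data: CohortTable, candidates, r_threshold: float = 0.5
                        ) -> CollinearityResult:
    """Drop the clinically harder-to-obtain member of each correlated pair.

    Pairwise Pearson r on pairwise-complete observations; pairs with
    |r| >= threshold are processed in decreasing |r| and the variable with
    the worse (numerically larger) clinical_priority is dropped.  A variable
    already dropped cannot cause further drops.
    """
    if not (0 < r_threshold <= 1):
        raise ConfigurationError("r_threshold must lie in (0, 1]")
    candidates = [c for c in data.columns if c in set(candidates)]
    corr = data.data[candidates].corr(method="pearson", min_periods=2)
    pairs = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= r_threshold:
                pairs.append((abs(r), a, b, float(r)))
    # decreasing |r|; lexicographic pair names for a deterministic order
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(candidates)
    dropped = []
    for _, a, b, r in pairs:
        if a not in alive or b not in alive:
            continue
        pa = data.spec(a).clinical_priority
        pb = data.spec(b).clinical_priority
        if pa is None or pb is None:
            raise ConfigurationError(
                f"clinical_priority required to arbitrate correlated pair ({a}, {b})")
        drop, keep = (a, b) if pa > pb else (b, a)
        alive.discard(drop)
        dropped.append((drop, keep, r))
    retained = tuple(c for c in candidates if c in alive)
    return CollinearityResult(retained, tuple(dropped))


# -- univariable screen ----------------------------------------------------

@dataclass(frozen=True)
class UnivariableResult:
    retained: tuple[str, ...]
    dropped: tuple[tuple[str, float], ...]    # (name, p) for dropped
    p_values: dict[str, float]


def univariable_screen(data: CohortTable, outcome: str, candidates,
                       alpha: float = 0.157) -> UnivariableResult:
    """One-predictor logistic screens; retain candidates with LRT p <= alpha.

    Categorical candidates are tested as whole dummy blocks.  Each candidate
    uses the rows complete on {outcome, candidate} (available-case), so the
    screen works on unimputed data too.  Perfect separation retains the
    candidate with p recorded as 0 and a warning.
    """
    candidates = [c for c in data.columns if c in set(candidates)]
    y_all = data.values(outcome)
    m_out = data.mask[outcome].to_numpy()
    retained, dropped = [], []
    pvalues: dict[str, float] = {}
    for name in candidates:
        m = m_out | data.mask[name].to_numpy()
        if m.any():
            sub = data.take_rows(np.flatnonzero(~m))
        else:
            sub = data
        y = sub.values(outcome)
        if np.unique(y).size < 2:
            raise DegenerateDataError(f"outcome one-class on rows complete for {name}")
        X, _, _ = build_design(sub, [name])
        _, ll0 = null_fit(y)
        beta, ll, _, conv = fit_irls(X, y)
        spec = data.spec(name)
        df = spec.n_levels - 1 if spec.measurement == "categorical" else 1
        if not conv:
            warnings.warn(f"separation fitting univariable model for {name}; "
                          "retained with p = 0", stacklevel=2)
            p = 0.0
        else:
            stat = max(0.0, 2.0 * (ll - ll0))
            p = float(stats.chi2.sf(stat, df))
        pvalues[name] = p
        (retained if p <= alpha else dropped).append((name, p))
    return UnivariableResult(tuple(n for n, _ in retained),
                             tuple(dropped), pvalues)


# -- power check -----------------------------------------------------------

def events_per_variable(data: CohortTable, outcome: str, n_candidates: int,
                        epv_min: float = 10.0) -> float:
    """Events per variable, with events = the minority outcome class.

    Emits a power warning when EPV <= ``epv_min`` (rule of thumb: analyses
    with EPV > 10 are considered sufficiently powered).
    """
    if n_candidates < 1:
        raise ConfigurationError("n_candidates must be >= 1")
    obs = data.observed(outcome)
    n1 = int(np.sum(obs == 1))
    n0 = int(np.sum(obs == 0))
    events = min(n1, n0)
    if events == 0:
        raise DegenerateDataError("no events in the outcome")
    epv = events / n_candidates
    if epv <= epv_min:
        warnings.warn(f"EPV = {epv:.1f} <= {epv_min:g}: analysis may be underpowered",
                      stacklevel=2)
    return epv


# -- assembled report ------------------------------------------------------

@dataclass(frozen=True)
class ScreenReport:
    retained: tuple[str, ...]
    dropped_collinear: tuple[tuple[str, str, float], ...]
    dropped_univariable: tuple[tuple[str, float], ...]
    epv: float

    def to_dict(self) -> dict:
        return {
            "retained": list(self.retained),
            "dropped_collinear": [list(t) for t in self.dropped_collinear],
            "dropped_univariable": [list(t) for t in self.dropped_univariable],
            "epv": self.epv,
        }


def screen(data: CohortTable, outcome: str, candidates, config) -> ScreenReport:
    """Full pre-selection chain: collinearity filter, univariable screen,
    events-per-variable check."""
    col = collinearity_filter(data, candidates, config.collinearity_r)
    uni = univariable_screen(data, outcome, col.retained, config.alpha_univariable)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        epv = events_per_variable(data, outcome, max(1, len(uni.retained)),
                                  config.epv_min)
    return ScreenReport(uni.retained, col.dropped, uni.dropped, epv)
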