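"""Logistic modeling, backward elimination, and pooling rules for
multiply-imputed model selection.

Backward elimination uses drop-one likelihood-ratio tests with a p-value
stopping rule (default alpha = 0.157, the level asymptotically comparable to
AIC for a single-parameter term).  Categorical predictors always enter and
leave as complete dummy blocks.

For multiply-imputed data, per-imputation selections are pooled by the
inclusion fraction (share of the m final models containing a predictor; a
predictor qualifies at >= 40% by default, i.e. at least 2 of 5 models) and
the qualified set is then confirmed by a pooled likelihood-ratio test across
imputations.  Pooled coefficients follow Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._logit import fit_irls, null_fit
from .cohort import AnalysisConfig, CohortTable, VariableSpec
from .errors import ConfigurationError, DegenerateDataError, NonConvergenceError


# -- design matrices -------------------------------------------------------

def build_design(data: CohortTable, predictors: list[str]):
    """Dense design matrix with intercept; categoricals as dummy blocks.

    Returns (X, col_names, blocks) where blocks maps each predictor to the
    list of its column indices in X (reference level = first declared level).
    """
    n = data.n
    cols = [np.ones(n)]
    names = ["(intercept)"]
    blocks: dict[str, list[int]] = {}
    for name in predictors:
        spec = data.spec(name)
        v = data.values(name)
        if spec.measurement == "categorical":
            idxs = []
            for lvl in range(1, spec.n_levels):
                cols.append((v == lvl).astype(float))
                names.append(f"{name}[{spec.levels[lvl]}]")
                idxs.append(len(cols) - 1)
            blocks[name] = idxs
        else:
            cols.append(v)
            names.append(name)
            blocks[name] = [len(cols) - 1]
    return np.column_stack(cols), names, blocks


def canonical_order(data: CohortTable, names) -> list[str]:
    """Fixed canonical predictor ordering: the spec/column order."""
    pos = {c: i for i, c in enumerate(data.columns)}
    return sorted(names, key=lambda x: pos[x])


# -- containers ------------------------------------------------------------

@dataclass(frozen=True)
class LogisticModel:
    """A fitted logistic model: predictor set, ML coefficients, likelihoods."""

    predictors: tuple[str, ...]
    coef_names: tuple[str, ...]          # dummy-expanded, incl. intercept
    params: np.ndarray                   # aligned with coef_names
    cov_params: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    n: int
    converged: bool

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def coefficients(self) -> dict[str, float]:
        return {nm: float(b) for nm, b in zip(self.coef_names[1:], self.params[1:])}

    def linear_predictor(self, data: CohortTable) -> np.ndarray:
        X, names, _ = build_design(data, list(self.predictors))
        if tuple(names) != self.coef_names:
            raise ConfigurationError("design mismatch when scoring new data")
        return X @ self.params

    def predicted_risk(self, data: CohortTable) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(data)))

    def loglik_on(self, data: CohortTable, outcome: str) -> float:
        """Log-likelihood of this (fixed-coefficient) model on other data."""
        eta = self.linear_predictor(data)
        y = data.values(outcome)
        return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


class ModelComposition(tuple):
    """A canonically ordered predictor set; equal sets compare equal."""

    def __new__(cls, names, canonical: list[str] | None = None):
        names = list(names)
        if canonical is not None:
            pos = {c: i for i, c in enumerate(canonical)}
            names = sorted(names, key=lambda x: pos[x])
        else:
            names = sorted(names)
        return super().__new__(cls, names)

    def label(self) -> str:
        return " + ".join(self) if self else "(intercept only)"


@dataclass(frozen=True)
class InclusionTable:
    """Per-predictor counts of appearance across a set of fitted models."""

    counts: dict[str, int]
    n_models: int

    @property
    def fractions(self) -> dict[str, float]:
        return {k: v / self.n_models for k, v in self.counts.items()}

    def qualified(self, threshold: float) -> list[str]:
        return [k for k, f in self.fractions.items() if f >= threshold]

    @staticmethod
    def from_models(compositions, candidates, n_models=None) -> "InclusionTable":
        compositions = list(compositions)
        n = n_models if n_models is not None else len(compositions)
        counts = {c: 0 for c in candidates}
        for comp in compositions:
            for name in comp:
                if name in counts:
                    counts[name] += 1
        return InclusionTable(counts, n)


# -- fitting ---------------------------------------------------------------

def fit_logistic(data: CohortTable, outcome: str, predictors) -> LogisticModel:
    """Maximum-likelihood logistic fit of ``outcome`` on ``predictors``.

    Non-convergence (separation) is reported via ``converged=False`` rather
    than an exception; callers in bootstrap loops flag such replicates.
    """
    predictors = list(predictors)
    used = [outcome] + predictors
    if bool(data.mask[used].to_numpy().any()):
        raise DegenerateDataError("missing cells among modeling columns; "
                                  "use complete cases or imputed data")
    y = data.values(outcome)
    uy = np.unique(y)
    if not np.isin(uy, (0.0, 1.0)).all() or uy.size < 2:
        raise DegenerateDataError("outcome must be binary with both classes present")
    _, ll0 = null_fit(y)
    if not predictors:
        b0, _ = null_fit(y)
        pbar = float(np.mean(y))
        cov = np.array([[1.0 / (data.n * pbar * (1 - pbar))]])
        return LogisticModel((), ("(intercept)",), np.array([b0]), cov,
                             ll0, ll0, data.n, True)
    X, names, _ = build_design(data, predictors)
    beta, ll, cov, conv = fit_irls(X, y)
    return LogisticModel(tuple(predictors), tuple(names), beta, cov,
                         ll, ll0, data.n, conv)


def lrt_drop_one(data: CohortTable, outcome: str, full: LogisticModel,
                 predictor: str) -> tuple[float, float]:
    """Likelihood-ratio test of dropping one predictor (whole dummy block).

    Returns (LR statistic, p-value); the statistic is clipped at zero for
    converged nested fits.
    """
    reduced_preds = [p for p in full.predictors if p != predictor]
    reduced = fit_logistic(data, outcome, reduced_preds)
    df = data.spec(predictor).n_levels - 1 if data.spec(predictor).measurement == "categorical" \
        else 1
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    return stat, float(stats.chi2.sf(stat, df))


@dataclass(frozen=True)
class BackwardResult:
    model: LogisticModel
    removal_trace: tuple[tuple[str, float], ...]   # (name, p at removal)


def _fit_cols(X: np.ndarray, y: np.ndarray, cols: list[int]):
    return fit_irls(X[:, cols], y)


def _backward_np(X: np.ndarray, y: np.ndarray, names: list[str],
                 blocks: dict[str, list[int]], dfs: dict[str, int],
                 alpha: float):
    """Numpy-level backward elimination on a prebuilt design matrix.

    Returns (surviving names, removal trace).  Raises NonConvergenceError on
    a non-converged full fit (separation).
    """
    current = list(names)
    trace: list[tuple[str, float]] = []
    while current:
        cols = [0] + [c for nm in current for c in blocks[nm]]
        _, ll_full, _, conv = _fit_cols(X, y, cols)
        if not conv:
            raise NonConvergenceError(
                f"separation/non-convergence fitting {current}",
                predictors=current)
        pvals = []
        for nm in current:
            red = [0] + [c for other in current if other != nm
                         for c in blocks[other]]
            _, ll_red, _, _ = _fit_cols(X, y, red)
            stat = max(0.0, 2.0 * (ll_full - ll_red))
            pvals.append(float(stats.chi2.sf(stat, dfs[nm])))
        pmax = max(pvals)
        if pmax <= alpha:
            return current, trace
        # tie-break: among maximal p, remove the later in canonical order
        worst = max(i for i, p in enumerate(pvals) if p >= pmax - 1e-12)
        trace.append((current[worst], pvals[worst]))
        current = current[:worst] + current[worst + 1:]
    return current, trace


def _univariable_np(X: np.ndarray, y: np.ndarray, names: list[str],
                    blocks: dict[str, list[int]], dfs: dict[str, int],
                    alpha: float) -> list[str]:
    """Numpy-level univariable screen (complete data): retain p <= alpha;
    a non-converged (separated) candidate is retained with p = 0."""
    _, ll0 = null_fit(y)
    kept = []
    for nm in names:
        cols = [0] + blocks[nm]
        _, ll, _, conv = _fit_cols(X, y, cols)
        if not conv:
            kept.append(nm)
            continue
        stat = max(0.0, 2.0 * (ll - ll0))
        if stats.chi2.sf(stat, dfs[nm]) <= alpha:
            kept.append(nm)
    return kept


def backward_eliminate(data: CohortTable, outcome: str, start,
                       alpha: float = 0.157) -> BackwardResult:
    """Backward elimination with a likelihood-ratio p-value stopping rule.

    At each step the predictor with the largest drop-one LRT p-value
    (categorical predictors as whole dummy blocks) is removed if that p
    exceeds ``alpha``; ties are broken by removing the predictor later in
    canonical (column) order, so the result is invariant to the ordering of
    ``start``.
    """
    if not start:
        raise ConfigurationError("backward elimination needs a non-empty start set")
    current = canonical_order(data, list(start))
    X, _, blocks = build_design(data, current)
    y = data.values(outcome)
    if bool(data.mask[[outcome] + current].to_numpy().any()):
        raise DegenerateDataError("missing cells among modeling columns")
    dfs = {nm: len(blocks[nm]) for nm in current}
    survivors, trace = _backward_np(X, y, current, blocks, dfs, alpha)
    return BackwardResult(fit_logistic(data, outcome, survivors), tuple(trace))


# -- pooled likelihood-ratio confirmation ----------------------------------

def pooled_lrt(stats_per_imp, df: int, method: str = "d2") -> float:
    """Pool per-imputation likelihood-ratio statistics into one p-value.

    ``d2``: combine the chi-square statistics with an average-relative-
    increase-in-variance correction and an F reference distribution
    (Li–Meng–Raghunathan–Rubin).  With m = 1 this reduces to the plain
    chi-square test.  ``median_p`` is a simple cross-check fallback.
    """
    d = np.asarray(stats_per_imp, dtype=float)
    m = d.size
    if method == "median_p":
        return float(np.median(stats.chi2.sf(d, df)))
    if m == 1:
        return float(stats.chi2.sf(d[0], df))
    dbar = d.mean()
    sq = np.sqrt(d)
    r = (1.0 + 1.0 / m) * sq.var(ddof=1)
    D = (dbar / df - (m + 1.0) / (m - 1.0) * r) / (1.0 + r)
    if D <= 0:
        return 1.0
    nu = df ** (-3.0 / m) * (m - 1.0) * (1.0 + 1.0 / r) ** 2 if r > 0 else np.inf
    return float(stats.f.sf(D, df, nu))


@dataclass
class MiSelectResult:
    """Outcome of inclusion-fraction model selection on imputed data."""
    models: list[LogisticModel]              # confirmed set refit per imputation
    inclusion: InclusionTable                # over the m per-imputation final models
    confirmed: list[str]
    per_imputation_selected: list[ModelComposition]
    screened_pool: list[str]
    dropped_confirmation: list[tuple[str, float]]


def mi_select(imps, outcome: str, candidates, config: AnalysisConfig) -> MiSelectResult:
    """Inclusion-fraction selection across multiply-imputed datasets.

    1. univariable screen within each completed dataset; a candidate enters
       the qualifying pool if screened-in in >= ``inclusion_threshold`` of
       the m datasets;
    2. backward elimination from the pool within each dataset;
    3. predictors appearing in >= ``inclusion_threshold`` of the m final
       models qualify;
    4. each qualified predictor is confirmed by a pooled drop-one LRT across
       imputations; non-significant ones are removed iteratively, largest
       pooled p first.
    """
    from .screening import univariable_screen  # local import: avoid cycle

    tables = imps.completed
    m = len(tables)
    candidates = canonical_order(tables[0], list(candidates))

    # step 1: per-imputation univariable screening -> qualifying pool
    screen_counts = {c: 0 for c in candidates}
    for t in tables:
        frag = univariable_screen(t, outcome, candidates, config.alpha_univariable)
        for name in frag.retained:
            screen_counts[name] += 1
    pool = [c for c in candidates if screen_counts[c] / m >= config.inclusion_threshold]

    # step 2: backward elimination in each completed dataset
    selections: list[ModelComposition] = []
    for t in tables:
        if pool:
            res = backward_eliminate(t, outcome, pool, config.alpha_backward)
            selections.append(ModelComposition(res.model.predictors, candidates))
        else:
            selections.append(ModelComposition((), candidates))

    inclusion = InclusionTable.from_models(selections, candidates)
    qualified = canonical_order(tables[0], inclusion.qualified(config.inclusion_threshold))

    # step 3: pooled-LRT confirmation, iterative largest-p-first removal
    dropped: list[tuple[str, float]] = []
    while qualified:
        pooled_ps = {}
        fulls = [fit_logistic(t, outcome, qualified) for t in tables]
        for name in qualified:
            df = (tables[0].spec(name).n_levels - 1
                  if tables[0].spec(name).measurement == "categorical" else 1)
            lrs = []
            for t, full in zip(tables, fulls):
                stat, _ = lrt_drop_one(t, outcome, full, name)
                lrs.append(stat)
            pooled_ps[name] = pooled_lrt(lrs, df, config.pooled_lrt)
        worst = max(qualified, key=lambda nm: (pooled_ps[nm], qualified.index(nm)))
        if pooled_ps[worst] <= config.alpha_lrt:
            break
        dropped.append((worst, pooled_ps[worst]))
        qualified = [q for q in qualified if q != worst]

    models = [fit_logistic(t, outcome, qualified) for t in tables]
    return MiSelectResult(models, inclusion, qualified, selections, pool, dropped)


# -- Rubin's rules ---------------------------------------------------------

@dataclass(frozen=True)
class PooledModel:
    coef_names: tuple[str, ...]
    estimates: np.ndarray
    within_variance: np.ndarray
    between_variance: np.ndarray
    total_variance: np.ndarray
    m: int


def pool_rubin(models: list[LogisticModel]) -> PooledModel:
    """Pool per-imputation coefficient estimates by Rubin's rules.

    pooled = mean of estimates; total variance = mean within-imputation
    variance + (1 + 1/m) x between-imputation variance.
    """
    if not models:
        raise ConfigurationError("nothing to pool")
    names = models[0].coef_names
    if any(mdl.coef_names != names for mdl in models):
        raise ConfigurationError("models must share an identical composition to pool")
    m = len(models)
    est = np.stack([mdl.params for mdl in models])
    wv = np.stack([np.diag(mdl.cov_params) for mdl in models])
    qbar = est.mean(axis=0)
    ubar = wv.mean(axis=0)
    b = est.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    total = ubar + (1.0 + 1.0 / m) * b
    return PooledModel(names, qbar, ubar, b, total, m)
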