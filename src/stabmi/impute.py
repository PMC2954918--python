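"""Multivariate Imputation by Chained Equations with predictive mean matching.

Each of m imputations runs an independent chained-equations loop: missing
cells are initialised by random draws from the observed marginals, then for
a fixed number of cycles every incomplete variable (visited in order of
increasing missingness) is regressed on all other variables and each missing
cell is filled with the observed value of a donor drawn uniformly from the
k cases whose predicted means lie closest to the target's predicted mean.

Matching is Type-1: donor predictions come from a Bayesian draw of the
regression coefficients, target predictions from the posterior-mean
coefficients, which propagates parameter uncertainty between imputations.
PMM is used for every measurement level (binary and categorical included),
so imputed values are always members of the variable's observed value set
and category codes stay plausible by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import ConfigurationError


@dataclass(frozen=True)
class ImputationResult:
    """m completed cohort tables plus per-chain convergence traces.

    ``trace[var]`` is an (m, n_iter, 2) array of the mean and SD of the
    imputed cells of ``var`` at each iteration of each chain.
    """
    completed: list[CohortTable]
    m: int
    iterations: int
    rng_seed: int
    trace: dict[str, np.ndarray]


def _bayes_ols(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """OLS with a Bayesian coefficient draw (normal-inverse-chi-square).

    Returns (beta_hat, beta_draw).  A singular normal matrix falls back to a
    small ridge with a warning.
    """
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    ridge = 0.0
    try:
        L = np.linalg.cholesky(XtX)
    except np.linalg.LinAlgError:
        ridge = 1e-6 * max(1.0, np.trace(XtX) / p)
        warnings.warn("singular conditional regression; ridge-stabilised",
                      stacklevel=3)
        L = np.linalg.cholesky(XtX + ridge * np.eye(p))
    beta_hat = np.linalg.solve(L.T, np.linalg.solve(L, Xty))
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    rss = float(resid @ resid)
    sigma2 = (rss + 1e-12) / rng.chisquare(df)
    # beta_draw ~ N(beta_hat, sigma2 * (X'X)^-1)
    z = rng.standard_normal(p)
    beta_draw = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    return beta_hat, beta_draw


def _pmm_fill(pred_obs, pred_mis, y_obs, k, rng):
    """For each target, draw a donor uniformly among the k closest predicted
    means and return the donor's observed value."""
    k = min(k, y_obs.size)
    out = np.empty(pred_mis.size)
    for i, pm in enumerate(pred_mis):
        d = np.abs(pred_obs - pm)
        if k < d.size:
            cand = np.argpartition(d, k - 1)[:k]
        else:
            cand = np.arange(d.size)
        out[i] = y_obs[cand[rng.integers(cand.size)]]
    return out


def impute(data: CohortTable, m: int = 5, n_iter: int = 10, k_donors: int = 5,
           seed: int = 0) -> ImputationResult:
    """Run MICE with predictive mean matching, producing m completed tables.

    All variables except declared ``id`` columns — including the outcome and
    auxiliaries — serve as predictors in every conditional model.  Each
    imputation uses an independent split of the seed, so the m chains are
    mutually independent and the whole run is reproducible.
    """
    if n_iter == 1:
        warnings.warn("single-iteration MICE run: chains cannot mix", stacklevel=2)
    use_cols = [s.name for s in data.specs if s.role != "id"]
    Y0 = data.data[use_cols].to_numpy().copy()
    M = data.mask[use_cols].to_numpy()
    n, p = Y0.shape
    miss_counts = M.sum(axis=0)
    incomplete = [j for j in np.argsort(miss_counts, kind="stable") if miss_counts[j] > 0]
    for j in incomplete:
        if n - miss_counts[j] < k_donors:
            raise ConfigurationError(
                f"variable {use_cols[j]!r} has fewer than k_donors={k_donors} "
                "observed values")

    trace = {use_cols[j]: np.full((m, n_iter, 2), np.nan) for j in incomplete}
    completed: list[CohortTable] = []
    child_seeds = np.random.SeedSequence(seed).spawn(m)

    if not incomplete:
        completed = [data.with_data(data.data.copy()) for _ in range(m)]
        return ImputationResult(completed, m, n_iter, seed, {})

    for chain, ss in enumerate(child_seeds):
        rng = np.random.default_rng(ss)
        Y = Y0.copy()
        # initialise missing cells from the observed marginals
        for j in incomplete:
            obs = Y0[~M[:, j], j]
            Y[M[:, j], j] = rng.choice(obs, size=int(miss_counts[j]), replace=True)
        for it in range(n_iter):
            for j in incomplete:
                others = [c for c in range(p) if c != j]
                X = np.column_stack([np.ones(n), Y[:, others]])
                obs_rows = ~M[:, j]
                mis_rows = M[:, j]
                beta_hat, beta_draw = _bayes_ols(X[obs_rows], Y[obs_rows, j], rng)
                pred_obs = X[obs_rows] @ beta_draw
                pred_mis = X[mis_rows] @ beta_hat
                Y[mis_rows, j] = _pmm_fill(pred_obs, pred_mis, Y0[obs_rows, j],
                                           k_donors, rng)
                imputed = Y[mis_rows, j]
                trace[use_cols[j]][chain, it] = (imputed.mean(),
                                                 imputed.std(ddof=0))
        filled = data.data.copy()
        filled[use_cols] = Y
        # id columns (if any) keep their original values and masking
        new_mask = data.mask.copy()
        new_mask[use_cols] = False
        completed.append(CohortTable(filled, data.specs, new_mask))
    return ImputationResult(completed, m, n_iter, seed, trace)


def convergence_trace(result: ImputationResult) -> dict[str, dict[str, np.ndarray]]:
    """Per-variable chain summaries for mixing diagnostics.

    Returns {variable: {'mean': (m, n_iter), 'sd': (m, n_iter)}}; empty for
    a no-missing input.
    """
    out = {}
    for var, arr in result.trace.items():
        out[var] = {"mean": arr[:, :, 0].copy(), "sd": arr[:, :, 1].copy()}
    return out


def export_completed(result: ImputationResult, directory, prefix: str = "imp") -> list[str]:
    """Write the m completed datasets as ``imp_1.csv`` ... ``imp_m.csv``."""
    import os
    from .cohort import write_cohort
    paths = []
    for i, table in enumerate(result.completed, start=1):
        path = os.path.join(str(directory), f"{prefix}_{i}.csv")
        write_cohort(table, path)
        paths.append(path)
    return paths
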