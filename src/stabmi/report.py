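"""Orchestration of the four modeling strategies and paper-style rendering.

The four strategies differ only in how missing data and selection
instability are handled:

* ``cca``  — complete-case analysis: drop incomplete subjects, screen,
  backward-eliminate, validate.
* ``mi``   — impute m datasets, select by inclusion fraction with pooled-LRT
  confirmation, validate per dataset and pool.
* ``b``    — complete cases plus the two-step bootstrap selection; the most
  frequently selected composition is the developed model.
* ``mi_b`` — the two-step bootstrap inside every imputed dataset, pooling
  all m x b2 tabulated models.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AnalysisConfig, CohortTable, complete_cases
from .errors import ConfigurationError
from .impute import ImputationResult, impute
from .performance import PerformanceReport, mi_performance, validate_optimism
from .screening import ScreenReport, screen
from .selection import (LogisticModel, ModelComposition, backward_eliminate,
                        canonical_order, fit_logistic, mi_select, pool_rubin)
from .stability import (FrequencyTable, StabilityResult, bootstrap_select,
                        mi_bootstrap_select)

METHODS = ("cca", "mi", "b", "mi_b")


@dataclass
class StrategyBundle:
    """Everything one strategy produced: screen log, model(s), stability
    description (bootstrap methods only), and validated performance."""

    method: str
    screen: ScreenReport
    models: list[LogisticModel]
    composition: ModelComposition
    stability: StabilityResult | None
    performance: PerformanceReport
    excluded_fraction: float
    manifest: dict = field(default_factory=dict)


def _seed_streams(seed: int, k: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(seed).spawn(k)]


def _column_scales(table: CohortTable, composition) -> dict[str, float]:
    """SD of each dummy-expanded design column, for standardized ranking."""
    from .selection import build_design
    if not composition:
        return {}
    X, names, _ = build_design(table, list(composition))
    return {nm: float(np.std(X[:, i])) for i, nm in enumerate(names) if i > 0}


def run_strategy(data: CohortTable, config: AnalysisConfig, method: str,
                 outcome: str | None = None, seed: int | None = None
                 ) -> StrategyBundle:
    """Execute the full chain for one strategy; deterministic given seed."""
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; use one of {METHODS}")
    outcome = outcome or data.outcome_name()
    seed = config.rng_seed if seed is None else seed
    candidates = data.candidates()
    s_imp, s_stab, s_val = _seed_streams(seed, 3)
    manifest = {"method": method, "seed": seed, "outcome": outcome,
                "n": data.n, "config": config.__dict__.copy()}

    if method in ("cca", "b"):
        cc = complete_cases(data, [outcome] + candidates)
        table = cc.table
        rep = screen(table, outcome, candidates, config)
        if method == "cca":
            if rep.retained:
                res = backward_eliminate(table, outcome, list(rep.retained),
                                         config.alpha_backward)
                model = res.model
            else:
                model = fit_logistic(table, outcome, [])
            comp = ModelComposition(model.predictors)
            perf = validate_optimism(table, outcome, comp, config, seed=s_val)
            manifest["column_sd"] = _column_scales(table, comp)
            return StrategyBundle(method, rep, [model], comp, None, perf,
                                  cc.excluded_fraction, manifest)
        # method == 'b': collinearity-filtered candidates feed the bootstrap;
        # the univariable screen is re-run inside every replicate
        from .screening import collinearity_filter
        col = collinearity_filter(table, candidates, config.collinearity_r)
        stab = bootstrap_select(table, outcome, list(col.retained), config,
                                seed=s_stab)
        comp = (stab.step2_frequencies.entries[0][0]
                if stab.step2_frequencies.entries else ModelComposition(()))
        model = fit_logistic(table, outcome, list(comp))
        perf = validate_optimism(table, outcome, comp, config, seed=s_val)
        manifest["column_sd"] = _column_scales(table, comp)
        return StrategyBundle(method, rep, [model], comp, stab, perf,
                              cc.excluded_fraction, manifest)

    # imputation-based strategies
    imps = impute(data, m=config.m_imputations, n_iter=config.n_iter,
                  k_donors=config.k_donors, seed=s_imp)
    # collinearity filter on the unimputed data (pairwise-complete r)
    from .screening import collinearity_filter, univariable_screen
    col = collinearity_filter(data, candidates, config.collinearity_r)
    rep = screen(imps.completed[0], outcome, candidates, config)
    cc = complete_cases(data, [outcome] + candidates)
    if method == "mi":
        sel = mi_select(imps, outcome, list(col.retained), config)
        comp = ModelComposition(sel.confirmed)
        perf = mi_performance(imps, outcome, comp, config, seed=s_val)
        manifest["column_sd"] = _column_scales(imps.completed[0], comp)
        return StrategyBundle(method, rep, sel.models, comp, None, perf,
                              cc.excluded_fraction, manifest)
    stab = mi_bootstrap_select(imps, outcome, list(col.retained), config,
                               seed=s_stab)
    comp = (stab.step2_frequencies.entries[0][0]
            if stab.step2_frequencies.entries else ModelComposition(()))
    models = [fit_logistic(t, outcome, list(comp)) for t in imps.completed]
    perf = mi_performance(imps, outcome, comp, config, seed=s_val)
    manifest["column_sd"] = _column_scales(imps.completed[0], comp)
    return StrategyBundle(method, rep, models, comp, stab, perf,
                          cc.excluded_fraction, manifest)


# -- rendering -------------------------------------------------------------

def _standardized_coefs(bundle: StrategyBundle) -> dict[str, float]:
    """|coefficient| x design-column SD, averaged over the bundle's models
    and over a categorical predictor's dummy block, for rank ordering of
    mixed-scale predictors.  Falls back to raw |coefficient| when the
    bundle carries no column scales (or when configured raw)."""
    sds = bundle.manifest.get("column_sd", {})
    out: dict[str, list[float]] = {}
    for model in bundle.models:
        for name, b in model.coefficients.items():
            base = name.split("[")[0]
            out.setdefault(base, []).append(abs(b) * sds.get(name, 1.0))
    return {k: float(np.mean(v)) for k, v in out.items()}


def composition_table(bundles: list[StrategyBundle]) -> pd.DataFrame:
    """Cross-strategy comparison of model compositions with per-strategy
    predictor ranks (1 = largest absolute standardized coefficient)."""
    all_preds: list[str] = []
    for b in bundles:
        for p in b.composition:
            if p not in all_preds:
                all_preds.append(p)
    tab = pd.DataFrame(index=all_preds)
    for b in bundles:
        coefs = _standardized_coefs(b)
        in_model = [p for p in all_preds if p in b.composition]
        ranked = sorted(in_model, key=lambda p: -coefs.get(p, 0.0))
        col = {p: (ranked.index(p) + 1 if p in ranked else np.nan)
               for p in all_preds}
        tab[b.method.upper()] = pd.Series(col)
    return tab


def frequency_table(freq: FrequencyTable, k: int = 5) -> pd.DataFrame:
    """Top-k most frequently selected models with Count and % rows
    (percent printed to 0.1)."""
    top = freq.top(k)
    preds: list[str] = []
    for comp, _, _ in top:
        for p in comp:
            if p not in preds:
                preds.append(p)
    cols = {}
    for i, (comp, count, pct) in enumerate(top, start=1):
        marks = ["X" if p in comp else "-" for p in preds]
        cols[str(i)] = marks + [count, round(pct, 1)]
    return pd.DataFrame(cols, index=preds + ["Count", "%"])


def performance_grid(bundles: list[StrategyBundle]) -> pd.DataFrame:
    """Performance rows (calibration slope, Nagelkerke R², apparent c with
    CI, optimism, corrected c) by strategy columns."""
    rows = ["calibration slope", "R2_N", "Ac", "Ac 95% CI", "Opt", "Oc"]
    cols = {}
    for b in bundles:
        p = b.performance
        cols[b.method.upper()] = [
            round(p.calibration_slope, 3),
            round(p.r2_nagelkerke, 3),
            round(p.apparent_c, 3),
            f"{p.c_ci_low:.3f},{p.c_ci_high:.3f}",
            round(p.optimism, 3),
            round(p.corrected_c, 3),
        ]
    return pd.DataFrame(cols, index=rows)


def render_tables(bundles: list[StrategyBundle], top_k: int = 5) -> str:
    """Plain-text report: composition comparison, per-strategy frequency
    tables, and the performance grid."""
    if not bundles:
        raise ConfigurationError("at least one strategy bundle is required")
    out = io.StringIO()
    print("== Model composition (rank by |standardized coefficient|) ==", file=out)
    print(composition_table(bundles).to_string(na_rep="-"), file=out)
    for b in bundles:
        if b.stability is not None and b.stability.step2_frequencies.entries:
            print(f"\n== Most frequently selected models ({b.method.upper()}) ==",
                  file=out)
            print(frequency_table(b.stability.step2_frequencies, top_k)
                  .to_string(), file=out)
    print("\n== Performance ==", file=out)
    print(performance_grid(bundles).to_string(), file=out)
    return out.getvalue()
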