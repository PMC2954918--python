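"""Two-step bootstrap model selection and selection-frequency tables.

Step 1 draws bootstrap resamples of the data and re-runs the whole
selection path (univariable screen, then backward elimination) in each;
predictors appearing in at least the inclusion-threshold fraction of the
resulting models qualify for step 2.  Step 2 draws fresh resamples from an
independent random stream and re-runs backward elimination restricted to the
qualified set; the resulting model compositions are tabulated into a
frequency table — the stability description of the selection procedure.

On multiply-imputed data the procedure runs inside each completed dataset
and the frequency table pools all m x b2 models (2500 at the defaults).

Replicates where the fit does not converge (separation in small resamples)
are counted and excluded from denominators, never redrawn: redrawing would
bias the tabulation toward well-behaved resamples.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .cohort import AnalysisConfig, CohortTable
from .errors import NonConvergenceError
from .impute import ImputationResult
from .screening import univariable_screen
from .selection import (InclusionTable, ModelComposition, backward_eliminate,
                        canonical_order)

_FAILURE_WARN_FRACTION = 0.05


@dataclass(frozen=True)
class FrequencyTable:
    """Model compositions with their bootstrap selection counts."""

    entries: tuple[tuple[ModelComposition, int, float], ...]  # (comp, count, %)
    total_models: int
    failed_replicates: int

    @staticmethod
    def from_compositions(comps, failed: int = 0) -> "FrequencyTable":
        comps = list(comps)
        total = len(comps)
        counts = Counter(comps)
        # count descending, ties lexicographic by composition
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], tuple(kv[0])))
        entries = tuple((comp, c, 100.0 * c / total if total else 0.0)
                        for comp, c in ordered)
        return FrequencyTable(entries, total, failed)

    def top(self, k: int = 5):
        return self.entries[:k]

    def inclusion_fraction(self, name: str) -> float:
        if self.total_models == 0:
            return 0.0
        hits = sum(c for comp, c, _ in self.entries if name in comp)
        return hits / self.total_models


def rank_predictors(freq: FrequencyTable, canonical: list[str] | None = None):
    """Per-predictor step-2 inclusion fraction and rank.

    Rank is by descending inclusion fraction; ties are resolved by canonical
    order so the ranking is deterministic.
    """
    names: list[str] = []
    for comp, _, _ in freq.entries:
        for nm in comp:
            if nm not in names:
                names.append(nm)
    if canonical is not None:
        pos = {c: i for i, c in enumerate(canonical)}
        names.sort(key=lambda x: pos.get(x, len(pos)))
    fracs = {nm: freq.inclusion_fraction(nm) for nm in names}
    ordered = sorted(names, key=lambda nm: (-fracs[nm], names.index(nm)))
    return [(nm, fracs[nm], rank + 1) for rank, nm in enumerate(ordered)]


@dataclass(frozen=True)
class StabilityResult:
    step1_inclusion: InclusionTable
    qualified: tuple[str, ...]
    step2_frequencies: FrequencyTable
    final_rank: tuple[tuple[str, float, int], ...]


# -- internals -------------------------------------------------------------

class _Prepared:
    """Design matrix prebuilt on the source table so bootstrap replicates
    only index numpy rows — no per-replicate DataFrame work."""

    def __init__(self, data: CohortTable, outcome: str, candidates: list[str]):
        from .selection import build_design
        self.names = list(candidates)
        self.X, _, self.blocks = build_design(data, self.names)
        self.y = data.values(outcome)
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("bootstrap selection requires complete data")
        self.dfs = {nm: len(self.blocks[nm]) for nm in self.names}


def _select_in_resample(prep: _Prepared, idx: np.ndarray,
                        config: AnalysisConfig) -> ModelComposition | None:
    """Screen + backward-eliminate inside one bootstrap resample.

    Returns the selected composition, or None when the replicate fails
    (one-class resampled outcome or non-convergence).
    """
    from .selection import _backward_np, _univariable_np
    y = prep.y[idx]
    if y.min() == y.max():
        return None
    X = prep.X[idx]
    try:
        kept = _univariable_np(X, y, prep.names, prep.blocks, prep.dfs,
                               config.alpha_univariable)
        if not kept:
            return ModelComposition(())
        survivors, _ = _backward_np(X, y, kept, prep.blocks, prep.dfs,
                                    config.alpha_backward)
        return ModelComposition(survivors)
    except NonConvergenceError:
        return None


def _fit_in_resample(prep: _Prepared, idx: np.ndarray, qualified,
                     config: AnalysisConfig) -> ModelComposition | None:
    """Backward elimination from the (fixed) qualified set in one resample."""
    from .selection import _backward_np
    y = prep.y[idx]
    if y.min() == y.max():
        return None
    if not qualified:
        return ModelComposition(())
    try:
        survivors, _ = _backward_np(prep.X[idx], y, list(qualified),
                                    prep.blocks, prep.dfs,
                                    config.alpha_backward)
        return ModelComposition(survivors)
    except NonConvergenceError:
        return None


def _step1(prep: _Prepared, config: AnalysisConfig, rng: np.random.Generator):
    comps, failed = [], 0
    n = prep.y.size
    for _ in range(config.b_step1):
        idx = rng.integers(0, n, n)
        comp = _select_in_resample(prep, idx, config)
        if comp is None:
            failed += 1
        else:
            comps.append(comp)
    return comps, failed


def step2_frequencies(data: CohortTable, outcome: str, qualified,
                      config: AnalysisConfig, rng: np.random.Generator
                      ) -> FrequencyTable:
    """Step-2 tabulation alone: fresh resamples, selection restricted to the
    given qualified set.  Exposed separately so the effect of shrinking the
    qualified set can be studied on a fixed resample stream."""
    qualified = list(qualified)
    prep = _Prepared(data, outcome, qualified)
    return _step2_prepared(prep, qualified, config, rng)


def _step2_prepared(prep: _Prepared, qualified, config: AnalysisConfig,
                    rng: np.random.Generator) -> FrequencyTable:
    comps, failed = [], 0
    n = prep.y.size
    for _ in range(config.b_step2):
        idx = rng.integers(0, n, n)
        comp = _fit_in_resample(prep, idx, qualified, config)
        if comp is None:
            failed += 1
        else:
            comps.append(comp)
    return FrequencyTable.from_compositions(comps, failed)


def _warn_failures(failed: int, total: int, stage: str):
    if total and failed / total > _FAILURE_WARN_FRACTION:
        warnings.warn(f"{failed}/{total} bootstrap replicates failed in {stage}",
                      stacklevel=3)


# -- public API ------------------------------------------------------------

def bootstrap_select(data: CohortTable, outcome: str, candidates,
                     config: AnalysisConfig, seed: int = 0) -> StabilityResult:
    """Two-step bootstrap model selection on a single (complete) dataset."""
    candidates = canonical_order(data, list(candidates))
    prep = _Prepared(data, outcome, candidates)
    ss1, ss2 = np.random.SeedSequence(seed).spawn(2)
    comps1, failed1 = _step1(prep, config, np.random.default_rng(ss1))
    _warn_failures(failed1, config.b_step1, "step 1")
    inclusion = InclusionTable.from_models(comps1, candidates)
    qualified = tuple(canonical_order(data, inclusion.qualified(config.inclusion_threshold)))
    if not qualified:
        warnings.warn("no predictor qualified after step 1; step 2 skipped",
                      stacklevel=2)
        empty = FrequencyTable.from_compositions([], 0)
        return StabilityResult(inclusion, qualified, empty, ())
    freq = _step2_prepared(prep, qualified, config, np.random.default_rng(ss2))
    _warn_failures(freq.failed_replicates, config.b_step2, "step 2")
    ranks = tuple(rank_predictors(freq, canonical=list(qualified)))
    return StabilityResult(inclusion, qualified, freq, ranks)


def mi_bootstrap_select(imps: ImputationResult, outcome: str, candidates,
                        config: AnalysisConfig, seed: int = 0) -> StabilityResult:
    """Two-step bootstrap selection across multiply-imputed datasets.

    With ``config.qualify == 'pooled'`` (default) step-1 qualification uses
    the pooled inclusion fraction over all m x b1 models; with ``'each'``
    a predictor must qualify within every completed dataset separately.
    The step-2 frequency table pools all m x b2 models.
    """
    tables = imps.completed
    m = len(tables)
    if m == 1:
        # single completed dataset: identical to the plain two-step procedure
        return bootstrap_select(tables[0], outcome, candidates, config, seed)
    candidates = canonical_order(tables[0], list(candidates))
    seeds = np.random.SeedSequence(seed).spawn(m)

    all_comps1: list[ModelComposition] = []
    per_set_qualified: list[set] = []
    failed1 = 0
    step2_rngs = []
    preps = [_Prepared(t, outcome, candidates) for t in tables]
    for prep, ss in zip(preps, seeds):
        ss1, ss2 = ss.spawn(2)
        comps, failed = _step1(prep, config, np.random.default_rng(ss1))
        failed1 += failed
        all_comps1.extend(comps)
        inc = InclusionTable.from_models(comps, candidates)
        per_set_qualified.append(set(inc.qualified(config.inclusion_threshold)))
        step2_rngs.append(np.random.default_rng(ss2))
    _warn_failures(failed1, m * config.b_step1, "step 1")

    pooled_inclusion = InclusionTable.from_models(all_comps1, candidates)
    if config.qualify == "each":
        qual_set = set.intersection(*per_set_qualified) if per_set_qualified else set()
        qualified = tuple(canonical_order(tables[0], qual_set))
    else:
        qualified = tuple(canonical_order(
            tables[0], pooled_inclusion.qualified(config.inclusion_threshold)))

    if not qualified:
        warnings.warn("no predictor qualified after step 1; step 2 skipped",
                      stacklevel=2)
        empty = FrequencyTable.from_compositions([], 0)
        return StabilityResult(pooled_inclusion, qualified, empty, ())

    comps2: list[ModelComposition] = []
    failed2 = 0
    for prep, rng in zip(preps, step2_rngs):
        ft = _step2_prepared(prep, qualified, config, rng)
        failed2 += ft.failed_replicates
        for comp, count, _ in ft.entries:
            comps2.extend([comp] * count)
    freq = FrequencyTable.from_compositions(comps2, failed2)
    _warn_failures(failed2, m * config.b_step2, "step 2")
    ranks = tuple(rank_predictors(freq, canonical=list(qualified)))
    return StabilityResult(pooled_inclusion, qualified, freq, ranks)
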