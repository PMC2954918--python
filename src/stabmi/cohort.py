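"""Cohort data model, CSV round-trip, and analysis configuration.

A :class:`CohortTable` is a subject-by-variable rectangle with an explicit
boolean missingness mask.  The mask is authoritative: every masked cell holds
NaN in the numeric payload so that downstream arithmetic cannot silently
consume a missing value, but the mask — not NaN-ness — is what the rest of
the package consults.

Categorical variables are stored as integer codes assigned from the declared
label order in the :class:`VariableSpec`, so codes are stable across files,
imputations and bootstrap replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DegenerateDataError, ParseError

ROLES = ("outcome_raw", "candidate", "auxiliary", "criterion", "id")
MEASUREMENTS = ("continuous", "binary", "categorical")

DEFAULT_MISSING_TOKENS = frozenset({"", "NA"})


@dataclass(frozen=True)
class VariableSpec:
    """Per-column metadata driving preprocessing and selection.

    Parameters
    ----------
    name:
        Column name, must match the CSV header.
    role:
        One of ``outcome_raw``, ``candidate``, ``auxiliary``, ``criterion``,
        ``id``.
    measurement:
        ``continuous``, ``binary`` or ``categorical``.
    levels:
        Ordered label list for categorical (or two-label binary) variables;
        labels are mapped to codes 0..k-1 in this order.
    clinical_priority:
        Positive integer rank among candidates; 1 = easiest to obtain in
        clinical practice.  Used by the collinearity filter to decide which
        of two correlated variables to keep.
    """

    name: str
    role: str
    measurement: str = "continuous"
    levels: tuple[str, ...] | None = None
    clinical_priority: int | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r} for {self.name}")
        if self.measurement not in MEASUREMENTS:
            raise ConfigurationError(
                f"unknown measurement {self.measurement!r} for {self.name}"
            )
        if self.measurement == "categorical" and not self.levels:
            raise ConfigurationError(f"categorical variable {self.name} needs levels")
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(l) for l in self.levels))
            if self.measurement == "binary" and len(self.levels) != 2:
                raise ConfigurationError(
                    f"binary variable {self.name} must declare exactly two labels"
                )
        if self.clinical_priority is not None and self.clinical_priority < 1:
            raise ConfigurationError(
                f"clinical_priority must be a positive rank ({self.name})"
            )

    @property
    def n_levels(self) -> int:
        if self.measurement == "categorical":
            return len(self.levels)
        return 2 if self.measurement == "binary" else 0


def validate_specs(specs: Sequence[VariableSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate variable names in spec list")
    outcomes = [s for s in specs if s.role == "outcome_raw"]
    if len(outcomes) > 1:
        raise ConfigurationError("more than one outcome_raw variable declared")
    prios = [s.clinical_priority for s in specs
             if s.role == "candidate" and s.clinical_priority is not None]
    if len(set(prios)) != len(prios):
        raise ConfigurationError("clinical_priority ranks must be unique among candidates")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the full modeling pipeline.

    Defaults are the conventional choices for this methodology: the 0.157
    significance level (asymptotically equivalent to AIC-based selection for
    a 1-df term) for the univariable screen, the backward-elimination
    stopping rule and the pooled-LRT confirmation; five imputations; 500+500
    two-step bootstrap samples; a 40% inclusion-fraction qualification
    threshold; 200 validation bootstrap samples; a Pearson ``r >= 0.5``
    collinearity trigger; and an events-per-variable floor of 10.
    """

    alpha_univariable: float = 0.157
    alpha_backward: float = 0.157
    alpha_lrt: float = 0.157
    m_imputations: int = 5
    n_iter: int = 10
    k_donors: int = 5
    b_step1: int = 500
    b_step2: int = 500
    inclusion_threshold: float = 0.40
    b_validation: int = 200
    collinearity_r: float = 0.5
    epv_min: float = 10.0
    rng_seed: int = 0
    qualify: str = "pooled"          # 'pooled' or 'each' (MI-5+B step-1 hand-off)
    pooled_lrt: str = "d2"           # 'd2' or 'median_p'
    validate: str = "refit"          # 'refit' or 'reselect'

    def __post_init__(self):
        for name in ("alpha_univariable", "alpha_backward", "alpha_lrt",
                     "inclusion_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ConfigurationError(f"{name} must lie in (0, 1); got {v}")
        for name in ("m_imputations", "n_iter", "k_donors",
                     "b_step1", "b_step2", "b_validation"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not (0 < self.collinearity_r <= 1):
            raise ConfigurationError("collinearity_r must lie in (0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        return cls(**dict(d))


class CohortTable:
    """Subject-by-variable table with an explicit missingness mask.

    ``data`` is an n x p float DataFrame (categoricals as integer codes);
    ``mask`` is a same-shaped boolean DataFrame, True where the cell is
    missing.  Masked cells hold NaN in ``data``.
    """

    def __init__(self, data: pd.DataFrame, specs: Sequence[VariableSpec],
                 mask: pd.DataFrame | None = None):
        validate_specs(specs)
        spec_names = [s.name for s in specs]
        missing_cols = set(spec_names) - set(data.columns)
        if missing_cols:
            raise ConfigurationError(f"data lacks spec'd columns: {sorted(missing_cols)}")
        data = data[spec_names].astype(float).reset_index(drop=True)
        if mask is None:
            mask = data.isna()
        else:
            mask = mask[spec_names].astype(bool).reset_index(drop=True)
            if mask.shape != data.shape:
                raise ConfigurationError("mask shape does not match data shape")
        if len(data) < 1:
            raise DegenerateDataError("cohort must contain at least one subject")
        # mask is authoritative: enforce NaN under the mask, reject stray NaN
        if bool((data.isna() & ~mask).any().any()):
            raise ConfigurationError("NaN cell not covered by the missingness mask")
        data = data.where(~mask, np.nan)
        self.data = data
        self.mask = mask
        self.specs = tuple(specs)
        self._spec_by_name = {s.name: s for s in specs}

    # -- introspection -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def spec(self, name: str) -> VariableSpec:
        try:
            return self._spec_by_name[name]
        except KeyError:
            raise ConfigurationError(f"no spec for column {name!r}") from None

    def candidates(self) -> list[str]:
        return [s.name for s in self.specs if s.role == "candidate"]

    def outcome_name(self) -> str:
        for s in self.specs:
            if s.role == "outcome_raw":
                return s.name
        raise ConfigurationError("no outcome_raw variable declared")

    def values(self, name: str) -> np.ndarray:
        """Column values as a float array (NaN where masked)."""
        return self.data[name].to_numpy()

    def observed(self, name: str) -> np.ndarray:
        """Non-missing values of one column."""
        col = self.data[name].to_numpy()
        return col[~self.mask[name].to_numpy()]

    def take_rows(self, idx: np.ndarray) -> "CohortTable":
        """Row-subset / resample (bootstrap indexing), preserving specs."""
        return CohortTable(self.data.iloc[idx].reset_index(drop=True),
                           self.specs,
                           self.mask.iloc[idx].reset_index(drop=True))

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        """Same specs, new (typically completed) payload."""
        return CohortTable(data, self.specs)

    def __eq__(self, other):
        if not isinstance(other, CohortTable):
            return NotImplemented
        obs_equal = ((self.data.to_numpy() == other.data.to_numpy())
                     | (self.mask.to_numpy() & other.mask.to_numpy()))
        return (self.specs == other.specs
                and self.data.shape == other.data.shape
                and bool((self.mask.to_numpy() == other.mask.to_numpy()).all())
                and bool(obs_equal.all()))


@dataclass(frozen=True)
class CompleteCases:
    """Output of complete-case restriction: the surviving table plus the
    fraction of subjects excluded for having at least one missing cell."""
    table: CohortTable
    excluded_fraction: float
    n_excluded: int


def complete_cases(data: CohortTable, columns: Iterable[str] | None = None) -> CompleteCases:
    """Drop every subject with a missing value on any of ``columns``.

    This is the complete-case analysis (CCA) restriction: only subjects with
    information on all analysis variables are retained.
    """
    columns = list(columns) if columns is not None else data.columns
    unknown = set(columns) - set(data.columns)
    if unknown:
        raise ConfigurationError(f"unknown columns: {sorted(unknown)}")
    any_missing = data.mask[columns].any(axis=1).to_numpy()
    keep = np.flatnonzero(~any_missing)
    if keep.size == 0:
        raise DegenerateDataError("no subject is complete on the selected columns")
    frac = 1.0 - keep.size / data.n
    return CompleteCases(data.take_rows(keep), frac, int(data.n - keep.size))


# -- CSV / config I/O ------------------------------------------------------

def read_cohort(csv_path, specs: Sequence[VariableSpec],
                missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS) -> CohortTable:
    """Read a cohort CSV under a variable spec.

    Cells whose raw token is in ``missing_tokens`` become masked; declared
    categorical/binary labels are mapped to integer codes in declared order;
    anything else must parse as a number.
    """
    missing_tokens = set(missing_tokens)
    if not missing_tokens:
        raise ConfigurationError("missing_tokens must be non-empty")
    validate_specs(specs)
    raw = pd.read_csv(csv_path, dtype=str, keep_default_na=False,
                      skipinitialspace=False)
    spec_names = [s.name for s in specs]
    absent = set(spec_names) - set(raw.columns)
    if absent:
        raise ConfigurationError(f"CSV header lacks spec'd column(s): {sorted(absent)}")
    n = len(raw)
    data = {}
    mask = {}
    for s in specs:
        tokens = raw[s.name].to_numpy()
        col = np.full(n, np.nan)
        miss = np.zeros(n, dtype=bool)
        label_map = {lab: float(i) for i, lab in enumerate(s.levels)} if s.levels else {}
        for i, tok in enumerate(tokens):
            t = tok.strip()
            if t in missing_tokens:
                miss[i] = True
                continue
            if t in label_map:
                col[i] = label_map[t]
                continue
            try:
                col[i] = float(t)
            except ValueError:
                raise ParseError(
                    f"row {i + 1}, column {s.name!r}: token {tok!r} is neither a "
                    f"missing token, a declared label, nor a number") from None
        if miss.all():
            raise DegenerateDataError(f"column {s.name!r} is entirely missing")
        data[s.name] = col
        mask[s.name] = miss
    return CohortTable(pd.DataFrame(data), specs, pd.DataFrame(mask))


def write_cohort(data: CohortTable, csv_path, missing_token: str = "NA") -> None:
    """Write a cohort to CSV; masked cells become ``missing_token``.

    Non-missing floats are written with shortest-round-trip repr so a
    write/read cycle reproduces them bit-identically.
    """
    out = data.data.copy()
    cols = {}
    for name in out.columns:
        vals = out[name].to_numpy()
        miss = data.mask[name].to_numpy()
        cols[name] = [missing_token if m else repr(float(v))
                      for v, m in zip(vals, miss)]
    pd.DataFrame(cols).to_csv(csv_path, index=False)


def specs_from_config(cfg: Mapping) -> list[VariableSpec]:
    """Build VariableSpecs from a parsed YAML/JSON config mapping."""
    specs = []
    for entry in cfg["variables"]:
        specs.append(VariableSpec(
            name=entry["name"],
            role=entry["role"],
            measurement=entry.get("measurement", "continuous"),
            levels=tuple(entry["levels"]) if entry.get("levels") else None,
            clinical_priority=entry.get("clinical_priority"),
        ))
    validate_specs(specs)
    return specs


def load_config(path) -> tuple[list[VariableSpec], AnalysisConfig]:
    """Load variable specs and analysis config from one YAML/JSON file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    specs = specs_from_config(cfg)
    analysis = AnalysisConfig.from_dict(cfg.get("analysis", {}))
    return specs, analysis
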