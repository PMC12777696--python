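"""Multi-wave panel data container, validation, eligibility filtering and reshaping.

The single input currency of the pipeline is :class:`PanelDataset`: a tidy
long-format table with one row per subject x wave, ten (or ``p``) ordinal item
columns coded 0-3, a baseline-age column, and optional per-subject covariates.
Cohort construction follows the usual longitudinal-survey rules: subjects must
appear in every wave, must have complete scale responses, and must satisfy a
minimum baseline age; remaining item-level missingness is handled by listwise
deletion (a subject with any missing cell is dropped entirely).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "CohortFilterSpec",
    "ExclusionLedger",
    "PanelValidationError",
    "SchemaError",
    "read_long_csv",
    "write_long_csv",
    "apply_eligibility",
    "listwise_delete",
    "to_wide",
    "from_wide",
]

#: canonical long-CSV column names
SUBJECT_COL = "subject_id"
WAVE_COL = "wave"
AGE_COL = "age_baseline"


class PanelValidationError(ValueError):
    """Raised when response values fall outside the allowed code range."""


class SchemaError(KeyError):
    """Raised when a mapped column is absent from the input file."""


@dataclass(frozen=True)
class CohortFilterSpec:
    """Eligibility rules applied to the raw panel.

    min_baseline_age
        Inclusive lower bound on age at the first wave, in years.
    require_all_waves
        Subject must have a row in every wave.
    require_complete_scale
        Subject must have no missing item response in any wave row present.
    """

    min_baseline_age: float = 60.0
    require_all_waves: bool = True
    require_complete_scale: bool = True

    def __post_init__(self) -> None:
        if self.min_baseline_age < 0:
            raise ValueError("min_baseline_age must be >= 0")


@dataclass
class ExclusionLedger:
    """Counts of excluded subjects attributed to the first failing criterion.

    Attribution order: (1) missing waves, (2) incomplete scale, (3) under age.
    """

    n_input: int = 0
    n_retained: int = 0
    counts: dict[str, int] = field(default_factory=lambda: {"missing_wave": 0, "incomplete_scale": 0, "age": 0})

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"n_input": self.n_input, "n_retained": self.n_retained, "excluded_by_reason": self.counts}, indent=2))


@dataclass
class PanelDataset:
    """Tidy subject x wave x item response panel.

    Parameters
    ----------
    data
        Long DataFrame with columns ``subject_id``, ``wave`` and one column per
        item; item codes are integers in {0,1,2,3} (NaN = missing).
    waves
        Ordered wave labels (strings); order defines the lag structure.
    items
        Ordered item column names.
    baseline_age
        Per-subject age at the first wave, indexed by subject id.
    extras
        Optional per-subject covariate DataFrame indexed by subject id.
    """

    data: pd.DataFrame
    waves: list[str]
    items: list[str]
    baseline_age: pd.Series
    extras: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("duplicate item names")
        if list(self.waves) != sorted(self.waves):
            raise ValueError("wave labels must be strictly increasing")
        missing_cols = [c for c in [SUBJECT_COL, WAVE_COL, *self.items] if c not in self.data.columns]
        if missing_cols:
            raise SchemaError(f"data is missing columns: {missing_cols}")
        bad = ~self.data[WAVE_COL].astype(str).isin(self.waves)
        if bad.any():
            raise ValueError(f"unknown wave labels: {sorted(self.data.loc[bad, WAVE_COL].unique())}")
        self._validate_codes()

    def _validate_codes(self) -> None:
        vals = self.data[self.items]
        ok = vals.isna() | vals.isin([0, 1, 2, 3])
        if not ok.all().all():
            rows = sorted(self.data.index[(~ok).any(axis=1)].tolist())
            raise PanelValidationError(f"item responses outside {{0,1,2,3}} in rows {rows[:20]}" + (" ..." if len(rows) > 20 else ""))

    # -- basic queries -----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data[SUBJECT_COL].nunique()

    @property
    def n_waves(self) -> int:
        return len(self.waves)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.data[SUBJECT_COL]))

    def wave_frame(self, wave: str) -> pd.DataFrame:
        """Item responses for one wave, indexed by subject id."""
        sub = self.data[self.data[WAVE_COL].astype(str) == str(wave)]
        return sub.set_index(SUBJECT_COL)[self.items]

    def complete_subjects(self) -> pd.Index:
        """Subjects present in every wave with no missing item response."""
        counts = self.data.groupby(SUBJECT_COL)[WAVE_COL].nunique()
        all_waves = counts.index[counts == self.n_waves]
        any_na = self.data[self.items].isna().any(axis=1)
        bad = pd.Index(self.data.loc[any_na, SUBJECT_COL].unique())
        return all_waves.difference(bad)

    def is_complete(self) -> bool:
        return len(self.complete_subjects()) == self.n_subjects and len(self.data) == self.n_subjects * self.n_waves

    def subset(self, subjects: Sequence) -> "PanelDataset":
        keep = self.data[SUBJECT_COL].isin(subjects)
        extras = self.extras.loc[self.extras.index.isin(subjects)] if self.extras is not None else None
        return replace(
            self,
            data=self.data.loc[keep].reset_index(drop=True),
            baseline_age=self.baseline_age.loc[self.baseline_age.index.isin(subjects)],
            extras=extras,
        )


DEFAULT_ITEMS = [f"cesd{i}" for i in range(1, 11)]


def _default_schema(items: Sequence[str]) -> dict[str, str]:
    return {SUBJECT_COL: SUBJECT_COL, WAVE_COL: WAVE_COL, AGE_COL: AGE_COL, **{it: it for it in items}}


def read_long_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    items: Sequence[str] | None = None,
    extra_cols: Sequence[str] = (),
) -> PanelDataset:
    """Read a long-format panel CSV into a validated :class:`PanelDataset`.

    ``schema`` maps canonical names (``subject_id``, ``wave``, ``age_baseline``,
    item names) to the CSV's column names; omitted entries default to identity.
    Missing responses may be empty cells or the string ``"NA"``. Out-of-range
    codes raise :class:`PanelValidationError` naming the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    items = list(items or DEFAULT_ITEMS)
    mapping = _default_schema(items)
    if schema:
        mapping.update(schema)
    df = pd.read_csv(path, dtype={mapping[SUBJECT_COL]: str, mapping[WAVE_COL]: str}, na_values=["NA"], keep_default_na=True)
    for canon in [SUBJECT_COL, WAVE_COL, AGE_COL, *items]:
        if mapping[canon] not in df.columns:
            raise SchemaError(f"column {mapping[canon]!r} (for {canon!r}) not found in {path.name}")
    rename = {v: k for k, v in mapping.items()}
    df = df.rename(columns=rename)
    waves = sorted(df[WAVE_COL].astype(str).unique())
    age = df.groupby(SUBJECT_COL)[AGE_COL].first().astype(float)
    extras = None
    extra_cols = [c for c in extra_cols if c in df.columns]
    if extra_cols:
        extras = df.groupby(SUBJECT_COL)[extra_cols].first()
    long = df[[SUBJECT_COL, WAVE_COL, *items]].copy()
    return PanelDataset(data=long, waves=waves, items=items, baseline_age=age, extras=extras)


def write_long_csv(data: PanelDataset, path: str | Path) -> None:
    """Write the long CSV (canonical column order, empty cell = missing)."""
    df = data.data.copy()
    df[AGE_COL] = df[SUBJECT_COL].map(data.baseline_age)
    cols = [SUBJECT_COL, WAVE_COL, AGE_COL, *data.items]
    if data.extras is not None:
        for c in data.extras.columns:
            df[c] = df[SUBJECT_COL].map(data.extras[c])
            cols.append(c)
    df = df.sort_values([SUBJECT_COL, WAVE_COL], kind="stable")
    out = df[cols].copy()
    for it in data.items:
        out[it] = out[it].astype("Int64")
    out.to_csv(path, index=False)


def apply_eligibility(data: PanelDataset, spec: CohortFilterSpec | None = None) -> tuple[PanelDataset, ExclusionLedger]:
    """Apply cohort eligibility rules; return the filtered panel and a ledger.

    A subject's exclusion is attributed to the first failing criterion in the
    order: participation in all waves, complete scale responses, minimum
    baseline age. The operation is idempotent.
    """
    spec = spec or CohortFilterSpec()
    ledger = ExclusionLedger(n_input=data.n_subjects)
    counts = data.data.groupby(SUBJECT_COL)[WAVE_COL].nunique()
    any_na = data.data[data.items].isna().any(axis=1)
    incomplete = set(data.data.loc[any_na, SUBJECT_COL].unique())
    keep = []
    for sid in data.subjects:
        if spec.require_all_waves and counts.get(sid, 0) < data.n_waves:
            ledger.counts["missing_wave"] += 1
        elif spec.require_complete_scale and sid in incomplete:
            ledger.counts["incomplete_scale"] += 1
        elif float(data.baseline_age.get(sid, np.nan)) < spec.min_baseline_age or np.isnan(data.baseline_age.get(sid, np.nan)):
            ledger.counts["age"] += 1
        else:
            keep.append(sid)
    ledger.n_retained = len(keep)
    if not keep:
        import warnings

        warnings.warn("eligibility filter retained no subjects", stacklevel=2)
    return data.subset(keep), ledger


def listwise_delete(data: PanelDataset) -> PanelDataset:
    """Drop every subject with any missing cell (or missing wave row)."""
    return data.subset(list(data.complete_subjects()))


def to_wide(data: PanelDataset) -> tuple[np.ndarray, list[str]]:
    """Stack waves into an ``N x (p*T)`` matrix, wave-major column order.

    Column labels are ``"item@wave"``. Requires complete data; run
    :func:`listwise_delete` first if any cell may be missing.
    """
    if not data.is_complete():
        raise ValueError("panel has missing cells or absent wave rows; apply listwise_delete first")
    subjects = data.subjects
    blocks = []
    labels: list[str] = []
    for w in data.waves:
        frame = data.wave_frame(w).loc[subjects]
        blocks.append(frame.to_numpy(dtype=float))
        labels.extend(f"{it}@{w}" for it in data.items)
    return np.hstack(blocks), labels


def from_wide(
    wide: np.ndarray,
    waves: Sequence[str],
    items: Sequence[str],
    subjects: Sequence | None = None,
    baseline_age: pd.Series | None = None,
) -> PanelDataset:
    """Inverse of :func:`to_wide` for integer-coded data."""
    wide = np.asarray(wide)
    T, p = len(waves), len(items)
    if wide.shape[1] != p * T:
        raise ValueError(f"expected {p * T} columns, got {wide.shape[1]}")
    n = wide.shape[0]
    subjects = list(subjects) if subjects is not None else [f"s{i:06d}" for i in range(n)]
    rows = []
    for t, w in enumerate(waves):
        block = wide[:, t * p : (t + 1) * p]
        df = pd.DataFrame(block, columns=list(items))
        df.insert(0, WAVE_COL, str(w))
        df.insert(0, SUBJECT_COL, subjects)
        rows.append(df)
    long = pd.concat(rows, ignore_index=True).sort_values([SUBJECT_COL, WAVE_COL], kind="stable").reset_index(drop=True)
    if baseline_age is None:
        baseline_age = pd.Series(np.full(n, np.nan), index=pd.Index(subjects, name=SUBJECT_COL))
    return PanelDataset(data=long, waves=[str(w) for w in waves], items=list(items), baseline_age=baseline_age)
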