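"""CESD-10 scoring, depression classification, prevalence and trend testing.

The 10-item Center for Epidemiological Studies Depression scale stores each
item as a frequency code 0 ("rarely or none of the time") to 3 ("most or all
of the time"). Two items (5 "hopeful about future" and 8 "happy" in the field
instrument) are phrased positively and reverse-scored: their severity
contribution is ``3 - code``. Totals range 0-30 and a total >= 10 classifies
a respondent as having depression.

Raw files always hold frequency codes; the reverse rule is applied at scoring
time only, so raw and scored data are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SUBJECT_COL, WAVE_COL, PanelDataset

__all__ = [
    "ScaleSpec",
    "PrevalenceResult",
    "TrendResult",
    "CESD10_LABELS",
    "score_total",
    "classify_depressed",
    "apply_reverse_scoring",
    "score_panel",
    "prevalence_wald",
    "wald_interval_from_proportion",
    "prevalence_by_wave",
    "cochran_armitage",
]

#: short descriptions of the ten items, keyed by 1-based item number
CESD10_LABELS = {
    1: "bothered by things",
    2: "trouble concentrating",
    3: "felt depressed",
    4: "everything was an effort",
    5: "hopeless about future",
    6: "felt fearful",
    7: "restless sleep",
    8: "felt unhappy",
    9: "felt lonely",
    10: "could not get going",
}


@dataclass(frozen=True)
class ScaleSpec:
    """Scoring rules for an ordinal symptom scale."""

    n_items: int = 10
    reverse_items: frozenset[int] = frozenset({5, 8})  # 1-based
    min_item: int = 0
    max_item: int = 3
    cutoff: int = 10

    def __post_init__(self) -> None:
        if not set(self.reverse_items) <= set(range(1, self.n_items + 1)):
            raise ValueError("reverse_items outside 1..n_items")
        if not 0 <= self.cutoff <= self.n_items * self.max_item:
            raise ValueError("cutoff outside achievable score range")

    @property
    def max_total(self) -> int:
        return self.n_items * self.max_item

    def reverse_mask(self) -> np.ndarray:
        m = np.zeros(self.n_items, dtype=bool)
        m[[i - 1 for i in self.reverse_items]] = True
        return m


def score_total(responses: Sequence[int] | np.ndarray, spec: ScaleSpec | None = None) -> np.ndarray | int:
    """Total severity score from raw frequency codes.

    Accepts a single response vector of length ``n_items`` or a 2-D array of
    shape ``(n, n_items)``. Reverse items contribute ``max_item - code``.
    """
    spec = spec or ScaleSpec()
    arr = np.asarray(responses)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != spec.n_items:
        raise ValueError(f"expected {spec.n_items} items, got {arr.shape[1]}")
    if np.isnan(arr.astype(float)).any():
        raise ValueError("missing item responses; apply listwise deletion upstream")
    if ((arr < spec.min_item) | (arr > spec.max_item)).any():
        raise ValueError(f"responses outside {{{spec.min_item}..{spec.max_item}}}")
    rev = spec.reverse_mask()
    sev = arr.astype(int).copy()
    sev[:, rev] = spec.max_item - sev[:, rev]
    totals = sev.sum(axis=1)
    return int(totals[0]) if single else totals


def classify_depressed(total: int | np.ndarray, spec: ScaleSpec | None = None) -> bool | np.ndarray:
    """True iff the total score meets the depression cutoff (>=)."""
    spec = spec or ScaleSpec()
    arr = np.asarray(total)
    if ((arr < 0) | (arr > spec.max_total)).any():
        raise ValueError("total score outside achievable range")
    out = arr >= spec.cutoff
    return bool(out) if np.isscalar(total) or arr.ndim == 0 else out


def apply_reverse_scoring(data: PanelDataset, spec: ScaleSpec | None = None) -> PanelDataset:
    """Return a panel whose item codes are severities (reverse items flipped).

    The network model is fitted to severity-coded items so that edge signs are
    interpretable on a common "more = worse" scale.
    """
    spec = spec or ScaleSpec()
    if data.n_items != spec.n_items:
        raise ValueError("scale spec does not match panel item count")
    df = data.data.copy()
    for idx in spec.reverse_items:
        col = data.items[idx - 1]
        df[col] = spec.max_item - df[col]
    out = PanelDataset(data=df, waves=data.waves, items=data.items, baseline_age=data.baseline_age, extras=data.extras)
    return out


def score_panel(data: PanelDataset, spec: ScaleSpec | None = None) -> pd.DataFrame:
    """Per subject x wave totals and depression status (long DataFrame)."""
    spec = spec or ScaleSpec()
    df = data.data.dropna(subset=data.items)
    totals = score_total(df[data.items].to_numpy(), spec)
    return pd.DataFrame(
        {
            SUBJECT_COL: df[SUBJECT_COL].to_numpy(),
            WAVE_COL: df[WAVE_COL].astype(str).to_numpy(),
            "total": totals,
            "depressed": totals >= spec.cutoff,
        }
    )


@dataclass(frozen=True)
class PrevalenceResult:
    wave: str
    n: int
    k: int
    prevalence: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95


@dataclass(frozen=True)
class TrendResult:
    z: float
    p_value: float
    scores: tuple[float, ...]
    statistic: float = field(default=float("nan"))  # chi-square = z**2


def wald_interval_from_proportion(p_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald interval p +/- z*sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    half = z * np.sqrt(p_hat * (1 - p_hat) / n)
    return max(0.0, p_hat - half), min(1.0, p_hat + half)


def prevalence_wald(k: int, n: int, level: float = 0.95, wave: str = "") -> PrevalenceResult:
    """Point prevalence k/n with a Wald normal-approximation interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    p = k / n
    lo, hi = wald_interval_from_proportion(p, n, level)
    return PrevalenceResult(wave=str(wave), n=int(n), k=int(k), prevalence=p, ci_low=lo, ci_high=hi, ci_level=level)


def prevalence_by_wave(data: PanelDataset, spec: ScaleSpec | None = None, level: float = 0.95) -> list[PrevalenceResult]:
    """Depression prevalence per wave among subjects with complete responses."""
    scored = score_panel(data, spec)
    out = []
    for w in data.waves:
        sub = scored[scored[WAVE_COL] == str(w)]
        out.append(prevalence_wald(int(sub["depressed"].sum()), len(sub), level, wave=w))
    return out


def cochran_armitage(counts: Sequence[tuple[int, int]], scores: Sequence[float] | None = None) -> TrendResult:
    """Cochran-Armitage test for a linear trend in proportions across waves.

    ``counts`` is a per-wave sequence of (k, n). With centered scores
    ``s~_w = s_w - sum(n_w s_w)/sum(n_w)`` the statistic is

        T = sum_w s~_w (k_w - n_w pbar),   Var T = pbar (1-pbar) sum_w n_w s~_w^2

    and ``z = T / sqrt(Var T)`` is compared with a standard normal
    (two-sided). Default scores are wave ranks 1..T; z is invariant to affine
    rescaling of the scores.
    """
    ks = np.array([c[0] for c in counts], dtype=float)
    ns = np.array([c[1] for c in counts], dtype=float)
    if len(ks) < 2:
        raise ValueError("need at least two waves")
    if (ns <= 0).any():
        raise ValueError("all denominators must be positive")
    if ((ks < 0) | (ks > ns)).any():
        raise ValueError("counts must satisfy 0 <= k <= n")
    s = np.arange(1.0, len(ks) + 1.0) if scores is None else np.asarray(scores, dtype=float)
    if len(s) != len(ks):
        raise ValueError("scores length must match waves")
    n_tot = ns.sum()
    pbar = ks.sum() / n_tot
    if pbar in (0.0, 1.0):
        raise ValueError("pooled proportion is degenerate (0 or 1); trend variance undefined")
    s_c = s - (ns * s).sum() / n_tot
    t_stat = float((s_c * (ks - ns * pbar)).sum())
    var_t = float(pbar * (1 - pbar) * (ns * s_c**2).sum())
    if var_t <= 0:
        raise ValueError("zero trend variance (identical scores)")
    z = t_stat / np.sqrt(var_t)
    p = 2 * stats.norm.sf(abs(z))
    return TrendResult(z=float(z), p_value=float(p), scores=tuple(s), statistic=float(z**2))
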