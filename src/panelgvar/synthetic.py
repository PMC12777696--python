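"""Seeded synthetic multi-wave ordinal panels with known panel-GVAR structure.

The generator is a latent-Gaussian threshold model whose continuous core is
exactly the fitted model: each subject draws a stable mean from the
between-subjects GGM, wave-1 deviations from the stationary within-person
distribution, and subsequent waves from the lag-1 recursion with
GGM-structured innovations. Latent scores are cut at per-item increasing
thresholds into codes {0,1,2,3}; reverse-keyed items are stored flipped
(``3 - bin``) so raw files mimic field coding and exercise the
reverse-scoring path. Optional MCAR masking emulates item-level missingness.

Default scenario constants mirror a four-wave ageing-cohort depression panel:
N = 1393 subjects, T = 4 waves, p = 10 items with reverse items {5, 8}, and
right-skewed item marginals (~55/25/12/8% across codes 0-3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import child_seed, min_eig, spectral_radius
from .panel import AGE_COL, SUBJECT_COL, WAVE_COL, PanelDataset
from .params import GGM, PanelGVARParams

__all__ = ["GroundTruth", "SimulatedPanel", "make_ground_truth", "simulate_panel", "inject_trend", "scenario", "bin_probabilities"]

#: cumulative probabilities of codes 0..2 implied by the default thresholds
DEFAULT_CODE_CUMPROBS = (0.55, 0.80, 0.92)

#: default study-scale constants
DEFAULT_N, DEFAULT_T, DEFAULT_P = 1393, 4, 10
DEFAULT_REVERSE = frozenset({5, 8})
DEFAULT_WAVES = ("2013", "2015", "2018", "2020")

#: structure seed shared by the named scenarios (data seed varies per run)
_SCENARIO_STRUCTURE_SEED = 20130415

#: per-wave uniform latent mean shifts (marginal-SD units) of the designed
#: rising-prevalence scenario; calibrated once by large-N simulation so the
#: wave depression prevalences sit near (0.37, 0.37, 0.42, 0.57)
TREND_SHIFTS = (0.139, 0.139, 0.190, 0.339)


@dataclass
class GroundTruth:
    """True generating parameters retained for recovery testing."""

    params: PanelGVARParams
    thresholds: np.ndarray | None  # p x 3 increasing cut points; None = continuous mode
    reverse_items: frozenset[int]  # 1-based
    n_subjects: int
    n_waves: int
    missing_rate: float = 0.0
    seed: int = 0
    wave_labels: tuple[str, ...] = DEFAULT_WAVES
    mean_shift_per_wave: np.ndarray | None = None  # T x p latent offsets
    nonstationary: bool = False

    def __post_init__(self) -> None:
        if self.thresholds is not None:
            thr = np.asarray(self.thresholds, dtype=float)
            if thr.shape != (self.params.p, 3) or np.any(np.diff(thr, axis=1) <= 0):
                raise ValueError("thresholds must be p x 3 strictly increasing")
            self.thresholds = thr
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if spectral_radius(self.params.beta) >= 1:
            raise ValueError("true temporal matrix must be stationary")
        if len(self.wave_labels) != self.n_waves:
            self.wave_labels = tuple(str(2013 + 2 * t) for t in range(self.n_waves))

    def marginal_sd(self) -> np.ndarray:
        """Stationary latent SD per item: sqrt(diag(Sigma_B + Sigma_eta))."""
        from .params import stationary_within_cov

        sigma_eta = stationary_within_cov(self.params.beta, self.params.contemporaneous.covariance())
        return np.sqrt(np.diag(self.params.between.covariance() + sigma_eta))

    def to_json(self, path: str | Path) -> None:
        obj = {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "n_waves": self.n_waves,
            "missing_rate": self.missing_rate,
            "reverse_items": sorted(self.reverse_items),
            "wave_labels": list(self.wave_labels),
            "nonstationary": self.nonstationary,
            "mu": self.params.mu.tolist(),
            "temporal": self.params.beta.tolist(),
            "contemporaneous_omega": self.params.contemporaneous.omega.tolist(),
            "contemporaneous_delta": self.params.contemporaneous.delta.tolist(),
            "between_omega": self.params.between.omega.tolist(),
            "between_delta": self.params.between.delta.tolist(),
            "thresholds": None if self.thresholds is None else self.thresholds.tolist(),
            "mean_shift_per_wave": None if self.mean_shift_per_wave is None else np.asarray(self.mean_shift_per_wave).tolist(),
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _sparse_omega(rng: np.random.Generator, p: int, n_edges: int, lo: float, hi: float, pos_prob: float = 0.85, max_tries: int = 50) -> np.ndarray:
    """Sparse PD-compatible partial-correlation matrix; redraw positions, then shrink."""
    iu = np.triu_indices(p, k=1)
    n_edges = min(n_edges, len(iu[0]))
    for _ in range(max_tries):
        omega = np.zeros((p, p))
        pick = rng.choice(len(iu[0]), size=n_edges, replace=False)
        mags = rng.uniform(lo, hi, size=n_edges)
        signs = np.where(rng.random(n_edges) < pos_prob, 1.0, -1.0)
        omega[iu[0][pick], iu[1][pick]] = mags * signs
        omega = omega + omega.T
        if min_eig(np.eye(p) - omega) > 0.05:
            return omega
    # positions exhausted: shrink the last draw until PD
    for _ in range(100):
        omega *= 0.9
        if min_eig(np.eye(p) - omega) > 0.05:
            return omega
    raise ValueError("could not build a positive-definite sparse GGM at this density")


def make_ground_truth(
    p: int = DEFAULT_P,
    density: float = 0.15,
    effect_range: tuple[float, float] = (0.1, 0.25),
    autoreg_range: tuple[float, float] = (0.2, 0.35),
    seed: int = 0,
    n_subjects: int = DEFAULT_N,
    n_waves: int = DEFAULT_T,
    missing_rate: float = 0.0,
    reverse_items: frozenset[int] | None = None,
    continuous: bool = False,
    delta_zeta: float = 1.0,
    delta_between: float = 1.2,
) -> GroundTruth:
    """Draw a sparse, stable, PD ground truth.

    ``density`` is the fraction of off-diagonal positions carrying an edge in
    each of B (cross-lags), the contemporaneous GGM and the between GGM;
    cross-lag magnitudes are sampled in ``effect_range`` with random sign,
    autoregressions in ``autoreg_range``. B is rescaled (cross-lags only) if
    its spectral radius exceeds 0.9. ``density = 0`` yields the documented
    autoregressive-only truth.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(child_seed(seed, 1))
    beta = np.diag(rng.uniform(*autoreg_range, size=p))
    n_cross = int(round(density * p * (p - 1)))
    if n_cross > 0:
        off_pos = [(j, i) for j in range(p) for i in range(p) if i != j]
        pick = rng.choice(len(off_pos), size=n_cross, replace=False)
        for k in pick:
            j, i = off_pos[k]
            beta[j, i] = rng.uniform(*effect_range) * (1 if rng.random() < 0.7 else -1)
        sr = spectral_radius(beta)
        if sr > 0.9:
            cross = beta - np.diag(np.diag(beta))
            beta = np.diag(np.diag(beta)) + cross * (0.9 / sr)
    n_ggm_edges = int(round(density * p * (p - 1) / 2))
    if n_ggm_edges > 0:
        omega_z = _sparse_omega(rng, p, n_ggm_edges, *effect_range)
        omega_b = _sparse_omega(rng, p, n_ggm_edges, *effect_range)
    else:
        omega_z = np.zeros((p, p))
        omega_b = np.zeros((p, p))
    params = PanelGVARParams(
        mu=np.zeros(p),
        beta=beta,
        contemporaneous=GGM(omega_z, np.full(p, float(delta_zeta))),
        between=GGM(omega_b, np.full(p, float(delta_between))),
    )
    truth = GroundTruth(
        params=params,
        thresholds=None,
        reverse_items=reverse_items if reverse_items is not None else (DEFAULT_REVERSE if p == DEFAULT_P else frozenset()),
        n_subjects=n_subjects,
        n_waves=n_waves,
        missing_rate=missing_rate,
        seed=seed,
    )
    if not continuous:
        truth.thresholds = default_thresholds(truth)
    return truth


def default_thresholds(truth: GroundTruth, cumprobs: tuple[float, float, float] = DEFAULT_CODE_CUMPROBS) -> np.ndarray:
    """Cut points putting each item's marginal code frequencies at ``cumprobs``."""
    sd = truth.marginal_sd()
    q = stats.norm.ppf(cumprobs)
    return truth.params.mu[:, None] + sd[:, None] * q[None, :]


def bin_probabilities(truth: GroundTruth, wave: int = 0) -> np.ndarray:
    """Closed-form p x 4 marginal code probabilities at one wave.

    Latent scores are normal with the stationary SD; a wave shift moves the
    mean. Used as the oracle for generator marginal checks.
    """
    if truth.thresholds is None:
        raise ValueError("continuous-mode truth has no thresholds")
    sd = truth.marginal_sd()
    mu = truth.params.mu.copy()
    if truth.mean_shift_per_wave is not None:
        mu = mu + np.asarray(truth.mean_shift_per_wave)[wave]
    z = (truth.thresholds - mu[:, None]) / sd[:, None]
    cum = stats.norm.cdf(z)
    probs = np.diff(np.concatenate([np.zeros((truth.params.p, 1)), cum, np.ones((truth.params.p, 1))], axis=1), axis=1)
    return probs


@dataclass
class SimulatedPanel:
    """Generator output: the coded panel plus the latent continuous panel."""

    dataset: PanelDataset | None  # None in continuous mode
    latent: np.ndarray  # N x (p*T), wave-major
    labels: list[str]
    truth: GroundTruth


def simulate_panel(truth: GroundTruth) -> SimulatedPanel:
    """Simulate the panel implied by ``truth`` (deterministic in its seed)."""
    params = truth.params
    p, T, n = params.p, truth.n_waves, truth.n_subjects
    from .params import stationary_within_cov

    sigma_b = params.between.covariance()
    sigma_zeta = params.contemporaneous.covariance()
    sigma_eta = stationary_within_cov(params.beta, sigma_zeta)
    rng = np.random.default_rng(child_seed(truth.seed, 2))
    m = rng.multivariate_normal(np.zeros(p), sigma_b, size=n, method="cholesky")
    eta = np.empty((T, n, p))
    eta[0] = rng.multivariate_normal(np.zeros(p), sigma_eta, size=n, method="cholesky")
    for t in range(1, T):
        zeta = rng.multivariate_normal(np.zeros(p), sigma_zeta, size=n, method="cholesky")
        eta[t] = eta[t - 1] @ params.beta.T + zeta
    shifts = np.zeros((T, p)) if truth.mean_shift_per_wave is None else np.asarray(truth.mean_shift_per_wave, dtype=float)
    latent = np.empty((n, p * T))
    for t in range(T):
        latent[:, t * p : (t + 1) * p] = params.mu + shifts[t] + m + eta[t]
    labels = [f"item{i + 1}@{w}" for w in truth.wave_labels for i in range(p)]
    if truth.thresholds is None:
        return SimulatedPanel(dataset=None, latent=latent, labels=labels, truth=truth)

    # ordinalize, flip reverse-keyed items, apply MCAR mask, assemble long table
    items = [f"cesd{i + 1}" for i in range(p)] if p == 10 else [f"item{i + 1}" for i in range(p)]
    rev_idx = [i - 1 for i in sorted(truth.reverse_items)]
    subjects = [f"s{i:06d}" for i in range(n)]
    age = 60.0 + np.floor(rng.gamma(shape=2.2, scale=3.6, size=n))
    frames = []
    for t, w in enumerate(truth.wave_labels):
        block = latent[:, t * p : (t + 1) * p]
        codes = np.empty((n, p), dtype=float)
        for i in range(p):
            codes[:, i] = np.searchsorted(truth.thresholds[i], block[:, i])
        codes[:, rev_idx] = 3 - codes[:, rev_idx]
        if truth.missing_rate > 0:
            mask = rng.random((n, p)) < truth.missing_rate
            codes[mask] = np.nan
        df = pd.DataFrame(codes, columns=items)
        df.insert(0, WAVE_COL, str(w))
        df.insert(0, SUBJECT_COL, subjects)
        frames.append(df)
    long = pd.concat(frames, ignore_index=True).sort_values([SUBJECT_COL, WAVE_COL], kind="stable").reset_index(drop=True)
    extras = pd.DataFrame(
        {
            "sex": np.where(rng.random(n) < 0.5463, "male", "female"),
            "married": (rng.random(n) < 0.8011).astype(int),
        },
        index=pd.Index(subjects, name=SUBJECT_COL),
    )
    ds = PanelDataset(
        data=long,
        waves=[str(w) for w in truth.wave_labels],
        items=items,
        baseline_age=pd.Series(age, index=pd.Index(subjects, name=SUBJECT_COL), name=AGE_COL),
        extras=extras,
    )
    return SimulatedPanel(dataset=ds, latent=latent, labels=labels, truth=truth)


def inject_trend(truth: GroundTruth, mean_shift_per_wave: np.ndarray) -> GroundTruth:
    """Variant with wave-specific latent mean offsets (T x p or length-T).

    A length-T vector is interpreted as a uniform shift of all items in units
    of each item's stationary marginal SD. The result is flagged
    non-stationary: a single-mean panel-GVAR no longer matches its mean
    structure, and downstream fitting should warn.
    """
    shifts = np.asarray(mean_shift_per_wave, dtype=float)
    if shifts.ndim == 1:
        if len(shifts) != truth.n_waves:
            raise ValueError("per-wave shift vector must have length T")
        shifts = shifts[:, None] * truth.marginal_sd()[None, :]
    if shifts.shape != (truth.n_waves, truth.params.p):
        raise ValueError("mean_shift_per_wave must be T x p")
    return replace(truth, mean_shift_per_wave=shifts, nonstationary=bool(np.any(shifts != 0)))


def recovery_ground_truth(seed: int = 0, n_subjects: int = 2000) -> GroundTruth:
    """Continuous-mode recovery testbed: p=6, T=4, sparse strong effects.

    B has autoregressions of 0.3 and six cross-lags of magnitude 0.2-0.28;
    each GGM carries five edges with |omega| in 0.25-0.35.
    """
    p = 6
    rng = np.random.default_rng(child_seed(seed, 3))
    for _ in range(100):
        beta = np.diag(np.full(p, 0.3))
        off_pos = [(j, i) for j in range(p) for i in range(p) if i != j]
        pick = rng.choice(len(off_pos), size=6, replace=False)
        for k in pick:
            j, i = off_pos[k]
            beta[j, i] = rng.uniform(0.2, 0.28) * (1 if rng.random() < 0.7 else -1)
        if spectral_radius(beta) <= 0.9:
            break
    omega_z = _sparse_omega(rng, p, 5, 0.25, 0.35)
    omega_b = _sparse_omega(rng, p, 5, 0.25, 0.35)
    params = PanelGVARParams(
        mu=np.zeros(p),
        beta=beta,
        contemporaneous=GGM(omega_z, np.ones(p)),
        between=GGM(omega_b, np.full(p, 1.2)),
    )
    return GroundTruth(params=params, thresholds=None, reverse_items=frozenset(), n_subjects=n_subjects, n_waves=4, seed=seed)


def scenario(name: str, seed: int = 0, n_subjects: int | None = None, missing_rate: float | None = None) -> GroundTruth:
    """Named study scenarios.

    ``default``
        N=1393, T=4, p=10 ordinal panel with sparse networks.
    ``null``
        Same scale but all edges zero (independence given the means).
    ``trend``
        Default structure plus the calibrated rising-prevalence mean shifts.
    ``recovery``
        Continuous-mode p=6 recovery testbed.

    The network structure of the named scenarios is fixed (internal structure
    seed); ``seed`` drives the sampling randomness.
    """
    if name == "recovery":
        t = recovery_ground_truth(seed=_SCENARIO_STRUCTURE_SEED, n_subjects=n_subjects or 2000)
        return replace(t, seed=seed)
    if name in ("default", "trend"):
        t = make_ground_truth(seed=_SCENARIO_STRUCTURE_SEED, n_subjects=n_subjects or DEFAULT_N, missing_rate=missing_rate or 0.0)
        t = replace(t, seed=seed)
        if name == "trend":
            t = inject_trend(t, np.array(TREND_SHIFTS))
        return t
    if name == "null":
        t = make_ground_truth(density=0.0, autoreg_range=(0.0, 0.0), seed=_SCENARIO_STRUCTURE_SEED, n_subjects=n_subjects or DEFAULT_N, missing_rate=missing_rate or 0.0)
        return replace(t, seed=seed)
    raise ValueError(f"unknown scenario {name!r}; choose default, null, trend or recovery")
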