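"""Panel-GVAR parameterization and its implied Gaussian moments.

The model for item vector :math:`y_{it}` (p items, T waves, N subjects) is

.. math::

    y_{it} = \\mu + m_i + \\eta_{it}, \\qquad
    \\eta_{it} = B \\eta_{i,t-1} + \\zeta_{it},

with subject effects :math:`m_i \\sim N(0, \\Sigma_B)` (between-subjects
network), innovations :math:`\\zeta_{it} \\sim N(0, \\Sigma_\\zeta)`
(contemporaneous network) and lag-1 coefficient matrix :math:`B` (temporal
network; entry ``b[j, i]`` is the effect of item i at wave t-1 on item j at
wave t, the diagonal holding autoregressions). Both covariances are
parameterized as Gaussian graphical models through their precisions,

.. math::

    K = \\Delta (I - \\Omega) \\Delta,

so the off-diagonal entries of :math:`\\Omega` are exactly the partial
correlations reported as network edge weights, and :math:`\\Delta` is a
positive diagonal scaling. The process is initialised at its stationary
distribution, so the stacked pT-vector of a subject's responses is Gaussian
with a mean of :math:`\\mu` repeated per wave and block covariance

.. math::

    \\operatorname{Cov}(y_t, y_s) = \\Sigma_B + B^{t-s} \\Sigma_\\eta
    \\quad (t \\ge s),

where :math:`\\Sigma_\\eta` solves the discrete Lyapunov equation
:math:`\\Sigma_\\eta = B \\Sigma_\\eta B^T + \\Sigma_\\zeta`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from ._utils import is_symmetric, min_eig, spectral_radius

__all__ = [
    "GGM",
    "ParamMasks",
    "PanelGVARParams",
    "ggm_precision",
    "ggm_covariance",
    "partial_correlations",
    "stationary_within_cov",
    "implied_moments",
    "neg2_loglik",
]

_PD_TOL = 1e-10


class StationarityError(ValueError):
    """Temporal matrix has spectral radius >= 1."""


class NotPositiveDefiniteError(ValueError):
    """A GGM or implied covariance fails its positive-definiteness check."""


@dataclass
class GGM:
    """Gaussian graphical model with partial-correlation edge weights.

    ``omega`` is the symmetric zero-diagonal matrix of partial correlations;
    ``delta`` the positive scaling vector. The implied precision is
    ``diag(delta) @ (I - omega) @ diag(delta)``.
    """

    omega: np.ndarray
    delta: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)

    @property
    def p(self) -> int:
        return self.omega.shape[0]

    def validate(self) -> None:
        if not is_symmetric(self.omega):
            raise ValueError("omega must be symmetric")
        if np.any(np.abs(np.diag(self.omega)) > 1e-12):
            raise ValueError("omega must have zero diagonal")
        if np.any(self.delta <= 0):
            raise ValueError("delta must be positive")
        if min_eig(np.eye(self.p) - self.omega) <= _PD_TOL:
            raise NotPositiveDefiniteError("I - omega is not positive definite")

    def precision(self) -> np.ndarray:
        return ggm_precision(self)

    def covariance(self) -> np.ndarray:
        return ggm_covariance(self)

    @classmethod
    def from_covariance(cls, sigma: np.ndarray) -> "GGM":
        """Recover (omega, delta) from a positive-definite covariance."""
        k = np.linalg.inv(np.asarray(sigma, dtype=float))
        delta = np.sqrt(np.diag(k))
        omega = np.eye(k.shape[0]) - k / np.outer(delta, delta)
        np.fill_diagonal(omega, 0.0)
        omega = (omega + omega.T) / 2
        return cls(omega=omega, delta=delta)


def ggm_precision(g: GGM) -> np.ndarray:
    """Precision ``K = diag(delta) (I - omega) diag(delta)``; checks PD."""
    g.validate()
    d = np.diag(g.delta)
    return d @ (np.eye(g.p) - g.omega) @ d


def ggm_covariance(g: GGM) -> np.ndarray:
    return np.linalg.inv(ggm_precision(g))


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Standard inversion identity: ``-K_ij / sqrt(K_ii K_jj)``, zero diag."""
    k = np.asarray(precision, dtype=float)
    d = np.sqrt(np.diag(k))
    pc = -k / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


@dataclass
class ParamMasks:
    """Free/fixed indicators for the prunable parameter matrices.

    True = free. Means and delta scalings are always free and carry no mask.
    ``omega_*`` masks are symmetric with a False diagonal; ``beta`` covers
    every lag-1 coefficient including the autoregressive diagonal.
    """

    beta: np.ndarray
    omega_zeta: np.ndarray
    omega_between: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=bool)
        self.omega_zeta = np.asarray(self.omega_zeta, dtype=bool)
        self.omega_between = np.asarray(self.omega_between, dtype=bool)
        for m in (self.omega_zeta, self.omega_between):
            if not np.array_equal(m, m.T) or np.any(np.diag(m)):
                raise ValueError("omega masks must be symmetric with False diagonal")

    @classmethod
    def saturated(cls, p: int) -> "ParamMasks":
        off = ~np.eye(p, dtype=bool)
        return cls(beta=np.ones((p, p), dtype=bool), omega_zeta=off.copy(), omega_between=off.copy())

    @property
    def p(self) -> int:
        return self.beta.shape[0]

    def n_free_edges(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(self.beta.sum() + self.omega_zeta[iu].sum() + self.omega_between[iu].sum())

    def copy(self) -> "ParamMasks":
        return ParamMasks(self.beta.copy(), self.omega_zeta.copy(), self.omega_between.copy())


@dataclass
class PanelGVARParams:
    """Full parameter set: means, temporal matrix and the two GGMs."""

    mu: np.ndarray
    beta: np.ndarray
    contemporaneous: GGM
    between: GGM
    masks: ParamMasks = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.masks is None:
            self.masks = ParamMasks.saturated(self.p)

    @property
    def p(self) -> int:
        return len(self.mu)

    @property
    def n_free(self) -> int:
        """Free parameters: mu and both deltas (always free) + free edges."""
        return 2 * self.p + self.p + self.masks.n_free_edges()

    def validate(self) -> None:
        self.contemporaneous.validate()
        self.between.validate()
        if spectral_radius(self.beta) >= 1.0:
            raise StationarityError("temporal matrix is non-stationary (spectral radius >= 1)")
        if np.any(self.beta[~self.masks.beta] != 0):
            raise ValueError("fixed temporal entries must be exactly zero")
        for omega, mask in ((self.contemporaneous.omega, self.masks.omega_zeta), (self.between.omega, self.masks.omega_between)):
            off = ~np.eye(self.p, dtype=bool)
            if np.any(omega[off & ~mask] != 0):
                raise ValueError("fixed omega entries must be exactly zero")

    def copy(self) -> "PanelGVARParams":
        return PanelGVARParams(
            mu=self.mu.copy(),
            beta=self.beta.copy(),
            contemporaneous=GGM(self.contemporaneous.omega.copy(), self.contemporaneous.delta.copy()),
            between=GGM(self.between.omega.copy(), self.between.delta.copy()),
            masks=self.masks.copy(),
        )

    def with_masks(self, masks: ParamMasks) -> "PanelGVARParams":
        """Re-mask, zeroing newly fixed entries."""
        out = self.copy()
        out.masks = masks.copy()
        out.beta[~masks.beta] = 0.0
        off = ~np.eye(self.p, dtype=bool)
        out.contemporaneous.omega[off & ~masks.omega_zeta] = 0.0
        out.between.omega[off & ~masks.omega_between] = 0.0
        return out


def stationary_within_cov(beta: np.ndarray, sigma_zeta: np.ndarray) -> np.ndarray:
    """Stationary within-person covariance: solves ``S = B S B' + Sigma_zeta``."""
    beta = np.asarray(beta, dtype=float)
    if spectral_radius(beta) >= 1.0:
        raise StationarityError("spectral radius >= 1; no stationary covariance")
    s = sla.solve_discrete_lyapunov(beta, np.asarray(sigma_zeta, dtype=float))
    return (s + s.T) / 2


def implied_moments(params: PanelGVARParams, T: int) -> tuple[np.ndarray, np.ndarray]:
    """Stacked mean (pT) and covariance (pT x pT) over T waves.

    Block (t, s) for t >= s is ``Sigma_B + B^(t-s) Sigma_eta``; diagonal
    blocks are ``Sigma_B + Sigma_eta``.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    params.validate()
    p = params.p
    sigma_zeta = params.contemporaneous.covariance()
    sigma_b = params.between.covariance()
    sigma_eta = stationary_within_cov(params.beta, sigma_zeta)
    mean = np.tile(params.mu, T)
    cov = np.empty((p * T, p * T))
    powers = [np.eye(p)]
    for _ in range(T - 1):
        powers.append(params.beta @ powers[-1])
    for t in range(T):
        for s in range(t + 1):
            block = sigma_b + powers[t - s] @ sigma_eta
            cov[t * p : (t + 1) * p, s * p : (s + 1) * p] = block
            if s != t:
                cov[s * p : (s + 1) * p, t * p : (t + 1) * p] = block.T
    cov = (cov + cov.T) / 2
    if min_eig(cov) <= 0:
        raise NotPositiveDefiniteError("implied stacked covariance is not positive definite")
    return mean, cov


def neg2_loglik(params: PanelGVARParams, sample_mean: np.ndarray, sample_cov: np.ndarray, n_subjects: int, T: int) -> float:
    """Gaussian deviance of the wide data under the implied moments.

    Equals ``-2 sum_i log phi(x_i; mu, Sigma)`` where the data enter through
    their sample mean and ML (denominator-N) covariance:

        N [ pT log 2pi + log|Sigma| + tr(S Sigma^-1) + d' Sigma^-1 d ].
    """
    mean, cov = implied_moments(params, T)
    pt = len(mean)
    chol = np.linalg.cholesky(cov)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    inv = sla.cho_solve((chol, True), np.eye(pt))
    d = np.asarray(sample_mean, dtype=float) - mean
    quad = float(d @ inv @ d)
    tr = float(np.sum(inv * np.asarray(sample_cov, dtype=float)))
    return n_subjects * (pt * np.log(2 * np.pi) + logdet + tr + quad)
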