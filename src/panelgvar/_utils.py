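"""Small shared helpers."""

from __future__ import annotations

import decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (report convention), not banker's."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def spectral_radius(b: np.ndarray) -> float:
    """Largest eigenvalue magnitude of a square matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(b, dtype=float)))))


def is_symmetric(a: np.ndarray, tol: float = 1e-10) -> bool:
    a = np.asarray(a)
    return a.ndim == 2 and a.shape[0] == a.shape[1] and bool(np.allclose(a, a.T, atol=tol))


def min_eig(a: np.ndarray) -> float:
    return float(np.min(np.linalg.eigvalsh(np.asarray(a, dtype=float))))


def child_seed(seed: int, *keys: int) -> int:
    """Derive a deterministic sub-seed below 2**31 from a parent seed and keys."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))
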