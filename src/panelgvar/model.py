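"""Maximum-likelihood panel-GVAR model and results objects.

``PanelGVAR`` is built from complete wide-format panel data (or a
:class:`~panelgvar.panel.PanelDataset`); ``fit`` maximises the stacked-wave
Gaussian likelihood and returns a :class:`PanelGVARResults` carrying the
three estimated networks, Wald standard errors, BIC and convergence
diagnostics. Model search (pruning and step-up) and centrality tables hang
off the results object.

Estimation operates on the wide sample mean and the denominator-N sample
covariance, which are sufficient statistics for the stacked Gaussian model.
Free parameters are the p stationary means, the unmasked lag-1 coefficients,
the unmasked partial-correlation edges of both GGMs, and the two positive
delta scalings (optimised on the log scale); masked edges are held at zero.
Positive-definiteness and stationarity are enforced by barrier rejection
inside the objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from ._utils import child_seed
from .panel import PanelDataset, to_wide
from .params import GGM, PanelGVARParams, ParamMasks, implied_moments, neg2_loglik

__all__ = ["PanelGVAR", "PanelGVARResults", "FitOptions"]

_PENALTY = 1e12


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for :meth:`PanelGVAR.fit`."""

    maxiter: int = 2000
    gtol: float = 1e-8
    ftol: float = 1e-12
    n_restarts: int = 0
    jitter: float = 0.05
    seed: int = 0


# ---------------------------------------------------------------------------
# parameter vector packing


class _Packer:
    """Maps between PanelGVARParams and a flat free-parameter vector.

    Order: mu, free beta entries (row-major), free upper-triangle omega_zeta,
    delta_zeta, free upper-triangle omega_between, delta_between. ``log_delta``
    selects the optimisation scale (log) or the natural scale used for the
    Wald Hessian.
    """

    def __init__(self, p: int, masks: ParamMasks, log_delta: bool = True):
        self.p = p
        self.masks = masks
        self.log_delta = log_delta
        self.iu = np.triu_indices(p, k=1)
        self.beta_idx = np.argwhere(masks.beta)
        self.oz_idx = [(i, j) for i, j in zip(*self.iu) if masks.omega_zeta[i, j]]
        self.ob_idx = [(i, j) for i, j in zip(*self.iu) if masks.omega_between[i, j]]
        self.n_params = p + len(self.beta_idx) + len(self.oz_idx) + p + len(self.ob_idx) + p

    def pack(self, params: PanelGVARParams) -> np.ndarray:
        dz = params.contemporaneous.delta
        db = params.between.delta
        f = np.log if self.log_delta else (lambda x: x)
        return np.concatenate(
            [
                params.mu,
                params.beta[self.masks.beta],
                [params.contemporaneous.omega[i, j] for i, j in self.oz_idx],
                f(dz),
                [params.between.omega[i, j] for i, j in self.ob_idx],
                f(db),
            ]
        )

    def unpack(self, theta: np.ndarray) -> PanelGVARParams:
        p = self.p
        pos = 0

        def take(k):
            nonlocal pos
            out = theta[pos : pos + k]
            pos += k
            return out

        mu = take(p).copy()
        beta = np.zeros((p, p))
        beta[self.masks.beta] = take(int(self.masks.beta.sum()))
        oz = np.zeros((p, p))
        for (i, j), v in zip(self.oz_idx, take(len(self.oz_idx))):
            oz[i, j] = oz[j, i] = v
        dz = take(p)
        ob = np.zeros((p, p))
        for (i, j), v in zip(self.ob_idx, take(len(self.ob_idx))):
            ob[i, j] = ob[j, i] = v
        db = take(p)
        if self.log_delta:
            dz, db = np.exp(dz), np.exp(db)
        return PanelGVARParams(
            mu=mu,
            beta=beta,
            contemporaneous=GGM(oz, np.asarray(dz, dtype=float).copy()),
            between=GGM(ob, np.asarray(db, dtype=float).copy()),
            masks=self.masks,
        )

    def bounds(self) -> list[tuple[float, float]]:
        b: list[tuple[float, float]] = [(-np.inf, np.inf)] * self.p
        b += [(-2.0, 2.0)] * len(self.beta_idx)
        b += [(-0.99, 0.99)] * len(self.oz_idx)
        b += [(-10.0, 10.0)] * self.p if self.log_delta else [(1e-4, 1e4)] * self.p
        b += [(-0.99, 0.99)] * len(self.ob_idx)
        b += [(-10.0, 10.0)] * self.p if self.log_delta else [(1e-4, 1e4)] * self.p
        return b


# ---------------------------------------------------------------------------
# fast deviance kernel (barrier-penalised; mirrors params.neg2_loglik)


def _ggm_cov_fast(omega: np.ndarray, delta: np.ndarray) -> np.ndarray | None:
    p = omega.shape[0]
    k = (np.eye(p) - omega) * np.outer(delta, delta)
    try:
        c = np.linalg.cholesky(k)
    except np.linalg.LinAlgError:
        return None
    return sla.cho_solve((c, True), np.eye(p))


def _deviance_kernel(
    mu: np.ndarray,
    beta: np.ndarray,
    oz: np.ndarray,
    dz: np.ndarray,
    ob: np.ndarray,
    db: np.ndarray,
    sample_mean: np.ndarray,
    sample_cov: np.ndarray,
    n: int,
    T: int,
) -> float:
    p = len(mu)
    ev = np.max(np.abs(np.linalg.eigvals(beta)))
    if ev >= 0.999:
        return _PENALTY * (1 + ev)
    sigma_zeta = _ggm_cov_fast(oz, dz)
    sigma_b = _ggm_cov_fast(ob, db)
    if sigma_zeta is None or sigma_b is None:
        return _PENALTY
    sigma_eta = sla.solve_discrete_lyapunov(beta, sigma_zeta)
    sigma_eta = (sigma_eta + sigma_eta.T) / 2
    cov = np.empty((p * T, p * T))
    block_power = sigma_eta
    for lag in range(T):
        blk = sigma_b + block_power if lag else sigma_b + sigma_eta
        for t in range(lag, T):
            s = t - lag
            cov[t * p : (t + 1) * p, s * p : (s + 1) * p] = blk
            if lag:
                cov[s * p : (s + 1) * p, t * p : (t + 1) * p] = blk.T
        block_power = beta @ block_power
    cov = (cov + cov.T) / 2
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return _PENALTY
    pt = p * T
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    inv = sla.cho_solve((chol, True), np.eye(pt))
    d = sample_mean - np.tile(mu, T)
    return float(n * (pt * np.log(2 * np.pi) + logdet + float(np.sum(inv * sample_cov)) + float(d @ inv @ d)))


# ---------------------------------------------------------------------------


class PanelGVAR:
    """Panel graphical VAR model for an N x (p*T) wide response matrix.

    Parameters
    ----------
    wide
        Complete wide data, wave-major column order (all items of wave 1,
        then wave 2, ...). Rows are subjects.
    n_items
        Number of items p.
    n_waves
        Number of waves T; ``wide.shape[1]`` must equal ``p * T``.
    item_names, wave_labels
        Optional display names.
    masks
        Default free/fixed masks (saturated if omitted).
    """

    def __init__(
        self,
        wide: np.ndarray,
        n_items: int,
        n_waves: int,
        item_names: Sequence[str] | None = None,
        wave_labels: Sequence[str] | None = None,
        masks: ParamMasks | None = None,
    ):
        wide = np.asarray(wide, dtype=float)
        if wide.ndim != 2 or wide.shape[1] != n_items * n_waves:
            raise ValueError(f"wide data must be N x {n_items * n_waves}")
        if np.isnan(wide).any():
            raise ValueError("wide data contains missing values; apply listwise deletion first")
        self.endog = wide
        self.p = int(n_items)
        self.T = int(n_waves)
        self.nobs = wide.shape[0]
        self.item_names = list(item_names) if item_names is not None else [f"y{i + 1}" for i in range(self.p)]
        self.wave_labels = [str(w) for w in wave_labels] if wave_labels is not None else [str(t + 1) for t in range(self.T)]
        self.masks = masks or ParamMasks.saturated(self.p)
        self.sample_mean = wide.mean(axis=0)
        centered = wide - self.sample_mean
        self.sample_cov = centered.T @ centered / self.nobs  # ML denominator N

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataset(cls, data: PanelDataset, masks: ParamMasks | None = None, reverse_score: bool = True, scale=None) -> "PanelGVAR":
        """Build from a complete :class:`PanelDataset`.

        With ``reverse_score`` (default) the reverse-keyed items are flipped to
        the severity scale before fitting, so all edges share a "more = worse"
        orientation.
        """
        if reverse_score:
            from .cesd import ScaleSpec, apply_reverse_scoring

            spec = scale or (ScaleSpec() if data.n_items == 10 else ScaleSpec(n_items=data.n_items, reverse_items=frozenset()))
            data = apply_reverse_scoring(data, spec)
        wide, _ = to_wide(data)
        return cls(wide, data.n_items, data.n_waves, item_names=data.items, wave_labels=data.waves, masks=masks)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, items: Sequence[str], subject_col: str = "subject_id", wave_col: str = "wave", masks: ParamMasks | None = None) -> "PanelGVAR":
        """Build from a complete long DataFrame (no reverse scoring applied)."""
        waves = sorted(df[wave_col].astype(str).unique())
        wide_blocks = []
        pivot = df.assign(**{wave_col: df[wave_col].astype(str)}).set_index([subject_col, wave_col])[list(items)].sort_index()
        subjects = pivot.index.get_level_values(0).unique()
        for w in waves:
            wide_blocks.append(pivot.xs(w, level=wave_col).loc[subjects].to_numpy(dtype=float))
        return cls(np.hstack(wide_blocks), len(items), len(waves), item_names=items, wave_labels=waves, masks=masks)

    # -- likelihood --------------------------------------------------------
    def deviance(self, params: PanelGVARParams) -> float:
        """Validated deviance (-2 log L) at ``params``."""
        return neg2_loglik(params, self.sample_mean, self.sample_cov, self.nobs, self.T)

    def loglike(self, params: PanelGVARParams) -> float:
        return -0.5 * self.deviance(params)

    def _objective(self, packer: _Packer):
        sm, sc, n, T = self.sample_mean, self.sample_cov, self.nobs, self.T

        def f(theta: np.ndarray) -> float:
            pr = packer.unpack(theta)
            return _deviance_kernel(pr.mu, pr.beta, pr.contemporaneous.omega, pr.contemporaneous.delta, pr.between.omega, pr.between.delta, sm, sc, n, T)

        return f

    # -- starting values ---------------------------------------------------
    def start_params(self, masks: ParamMasks | None = None) -> PanelGVARParams:
        """Moment-based starting values.

        Between covariance is initialised from the average lag>=2 cross-wave
        block (where within-person dependence has largely decayed), the
        within covariance from the diagonal blocks, and B from the lag-1
        blocks; everything is converted to the GGM parameterization and
        masked entries are zeroed.
        """
        masks = masks or self.masks
        p, T = self.p, self.T
        blocks = {(t, s): self.sample_cov[t * p : (t + 1) * p, s * p : (s + 1) * p] for t in range(T) for s in range(T)}
        mu0 = self.sample_mean.reshape(T, p).mean(axis=0)
        far = [blocks[(t, s)] for t in range(T) for s in range(T) if t - s >= 2]
        if far:
            sigma_b0 = sum(far) / len(far)
        else:
            sigma_b0 = 0.5 * blocks[(1, 0)]
        sigma_b0 = (sigma_b0 + sigma_b0.T) / 2
        diag_avg = sum(blocks[(t, t)] for t in range(T)) / T
        w = _nearest_pd(diag_avg - sigma_b0)
        lag1 = sum(blocks[(t + 1, t)] for t in range(T - 1)) / (T - 1) - sigma_b0
        b0 = lag1 @ np.linalg.pinv(w)
        ev = np.max(np.abs(np.linalg.eigvals(b0)))
        if ev > 0.8:
            b0 *= 0.8 / ev
        sigma_zeta0 = _nearest_pd(w - b0 @ w @ b0.T)
        sigma_b0 = _nearest_pd(sigma_b0)
        gz = _shrunk_ggm(GGM.from_covariance(sigma_zeta0))
        gb = _shrunk_ggm(GGM.from_covariance(sigma_b0))
        start = PanelGVARParams(mu=mu0, beta=b0, contemporaneous=gz, between=gb)
        return start.with_masks(masks)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        masks: ParamMasks | None = None,
        start: PanelGVARParams | None = None,
        options: FitOptions | None = None,
    ) -> "PanelGVARResults":
        """Maximise the likelihood; returns a :class:`PanelGVARResults`.

        Optimisation uses L-BFGS-B over the transformed free-parameter vector
        with up to ``options.n_restarts`` additional seeded jittered starts;
        the best optimum is kept and refits from jittered starts agreeing to
        ~1e-4 in deviance is the expected behaviour on well-posed problems.
        """
        opts = options or FitOptions()
        masks = masks or self.masks
        packer = _Packer(self.p, masks, log_delta=True)
        if start is not None:
            start = start.with_masks(masks)
        else:
            start = self.start_params(masks)
        f = self._objective(packer)
        theta0 = packer.pack(start)
        best = None
        rng = np.random.default_rng(child_seed(opts.seed, 7101))
        starts = [theta0]
        for _ in range(opts.n_restarts):
            starts.append(theta0 + rng.normal(scale=opts.jitter, size=theta0.shape))
        for th in starts:
            res = optimize.minimize(
                f,
                th,
                method="L-BFGS-B",
                bounds=packer.bounds(),
                options={"maxiter": opts.maxiter, "ftol": opts.ftol, "gtol": opts.gtol, "maxfun": 10 * opts.maxiter * max(1, len(th))},
            )
            if best is None or res.fun < best.fun:
                best = res
        est = packer.unpack(best.x)
        converged = bool(best.success) and np.isfinite(best.fun) and best.fun < _PENALTY / 2
        if best.fun >= _PENALTY / 2:
            warnings.warn("optimizer terminated inside the infeasible barrier region", stacklevel=2)
        return PanelGVARResults(model=self, params=est, deviance=float(best.fun), converged=converged, optimizer_message=str(best.message), options=opts)


def _nearest_pd(a: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Eigenvalue-floored symmetric projection (keeps moment inits feasible)."""
    a = (a + a.T) / 2
    vals, vecs = np.linalg.eigh(a)
    vals = np.maximum(vals, floor)
    return vecs @ np.diag(vals) @ vecs.T


def _shrunk_ggm(g: GGM, max_abs: float = 0.95) -> GGM:
    omega = np.clip(g.omega, -max_abs, max_abs)
    for _ in range(100):
        if np.min(np.linalg.eigvalsh(np.eye(g.p) - omega)) > 1e-6:
            break
        omega *= 0.9
    return GGM(omega=omega, delta=np.clip(g.delta, 1e-3, 1e3))


# ---------------------------------------------------------------------------


@dataclass
class PanelGVARResults:
    """Fitted panel-GVAR: estimates, uncertainty, fit indices, diagnostics."""

    model: PanelGVAR
    params: PanelGVARParams
    deviance: float
    converged: bool
    optimizer_message: str = ""
    options: FitOptions = field(default_factory=FitOptions)
    label: str = "fit"
    _se_cache: dict | None = field(default=None, repr=False)

    # -- fit indices -------------------------------------------------------
    @property
    def llf(self) -> float:
        return -0.5 * self.deviance

    @property
    def n_free(self) -> int:
        return self.params.n_free

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def bic(self) -> float:
        """k ln(N) - 2 logL with N = subjects (the independent units)."""
        return self.n_free * np.log(self.nobs) - 2 * self.llf

    @property
    def aic(self) -> float:
        return 2 * self.n_free - 2 * self.llf

    # -- standard errors ---------------------------------------------------
    def _compute_se(self) -> dict:
        """Wald standard errors from the numeric Hessian of deviance/2.

        The Hessian is taken on the natural parameter scale (delta, not log
        delta) with statsmodels' central differences; a non-PD Hessian marks
        the standard errors unavailable (NaN) rather than failing.
        """
        packer = _Packer(self.model.p, self.params.masks, log_delta=False)
        theta = packer.pack(self.params)
        sm, sc, n, T = self.model.sample_mean, self.model.sample_cov, self.model.nobs, self.model.T

        def half_dev(th):
            pr = packer.unpack(th)
            return 0.5 * _deviance_kernel(pr.mu, pr.beta, pr.contemporaneous.omega, pr.contemporaneous.delta, pr.between.omega, pr.between.delta, sm, sc, n, T)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(theta, half_dev)
        se_vec = np.full(len(theta), np.nan)
        available = False
        try:
            cov = np.linalg.inv(hess)
            diag = np.diag(cov)
            if np.all(np.isfinite(diag)) and np.all(diag > 0):
                se_vec = np.sqrt(diag)
                available = True
        except np.linalg.LinAlgError:
            pass
        return {"packer": packer, "se_vec": se_vec, "available": available}

    @property
    def se_available(self) -> bool:
        if self._se_cache is None:
            self._se_cache = self._compute_se()
        return self._se_cache["available"]

    @property
    def se(self) -> PanelGVARParams:
        """Standard errors arranged like the parameter set (NaN where fixed)."""
        if self._se_cache is None:
            self._se_cache = self._compute_se()
        packer: _Packer = self._se_cache["packer"]
        se_params = packer.unpack(self._se_cache["se_vec"])
        se_params.beta[~self.params.masks.beta] = np.nan
        off = ~np.eye(self.model.p, dtype=bool)
        se_params.contemporaneous.omega[off & ~self.params.masks.omega_zeta] = np.nan
        se_params.between.omega[off & ~self.params.masks.omega_between] = np.nan
        return se_params

    def edge_table(self) -> pd.DataFrame:
        """All free edges with estimate, se, Wald z and two-sided p.

        Temporal rows are directed (``from`` at wave t-1 predicting ``to`` at
        wave t, ``from == to`` marking autoregressions); GGM rows are
        undirected i<j pairs.
        """
        se = self.se if self.se_available else None
        names = self.model.item_names
        p = self.model.p
        rows = []

        def add(network, i, j, est, se_val):
            z = est / se_val if se_val is not None and np.isfinite(se_val) and se_val > 0 else np.nan
            pv = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({"network": network, "from": names[i], "to": names[j], "weight": est, "se": se_val if se_val is not None else np.nan, "z": z, "p": pv})

        for j in range(p):
            for i in range(p):
                if self.params.masks.beta[j, i]:
                    add("temporal", i, j, self.params.beta[j, i], se.beta[j, i] if se else None)
        for omega, mask, net in (
            (self.params.contemporaneous.omega, self.params.masks.omega_zeta, "contemporaneous"),
            (self.params.between.omega, self.params.masks.omega_between, "between"),
        ):
            se_omega = None
            if se:
                se_omega = se.contemporaneous.omega if net == "contemporaneous" else se.between.omega
            for i in range(p):
                for j in range(i + 1, p):
                    if mask[i, j]:
                        add(net, i, j, omega[i, j], se_omega[i, j] if se_omega is not None else None)
        return pd.DataFrame(rows)

    # -- networks ----------------------------------------------------------
    @property
    def temporal_network(self) -> np.ndarray:
        """Lag-1 coefficient matrix B (b[j, i]: item i -> item j)."""
        return self.params.beta

    @property
    def contemporaneous_network(self) -> np.ndarray:
        return self.params.contemporaneous.omega

    @property
    def between_network(self) -> np.ndarray:
        return self.params.between.omega

    def standardized_temporal(self) -> np.ndarray:
        """Secondary export: B rescaled by stationary within-person SDs."""
        from .params import stationary_within_cov

        sigma_eta = stationary_within_cov(self.params.beta, self.params.contemporaneous.covariance())
        sd = np.sqrt(np.diag(sigma_eta))
        return self.params.beta * (sd[None, :] / sd[:, None])

    def implied_moments(self) -> tuple[np.ndarray, np.ndarray]:
        return implied_moments(self.params, self.model.T)

    # -- search / centrality delegation ------------------------------------
    def prune(self, alpha: float = 0.05) -> "PanelGVARResults":
        from .search import prune

        return prune(self, alpha=alpha)

    def stepup(self, alpha: float = 0.05, max_steps: int | None = None):
        from .search import stepup

        return stepup(self, alpha=alpha, max_steps=max_steps)

    def centrality(self):
        from .centrality import centrality_tables

        return centrality_tables(self)

    def plot_network(self, which: str = "temporal", ax=None):
        """Quick circular-layout rendering of one network (matplotlib axis)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        import networkx as nx

        g = self.to_networkx(which)
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        pos = nx.circular_layout(g)
        weights = [abs(d["weight"]) * 8 for _, _, d in g.edges(data=True)]
        colors = ["tab:blue" if d["weight"] >= 0 else "tab:red" for _, _, d in g.edges(data=True)]
        nx.draw_networkx(g, pos=pos, ax=ax, node_color="lightgray", width=weights, edge_color=colors, with_labels=True, font_size=8)
        ax.set_title(f"{which} network")
        ax.set_axis_off()
        return ax

    def to_networkx(self, which: str = "temporal"):
        """Export one network as a (di)graph with signed ``weight`` edges."""
        import networkx as nx

        names = self.model.item_names
        if which == "temporal":
            g = nx.DiGraph()
            g.add_nodes_from(names)
            b = self.params.beta
            for j in range(self.model.p):
                for i in range(self.model.p):
                    if b[j, i] != 0:
                        g.add_edge(names[i], names[j], weight=float(b[j, i]))
            return g
        omega = {"contemporaneous": self.params.contemporaneous.omega, "between": self.params.between.omega}[which]
        g = nx.Graph()
        g.add_nodes_from(names)
        for i in range(self.model.p):
            for j in range(i + 1, self.model.p):
                if omega[i, j] != 0:
                    g.add_edge(names[i], names[j], weight=float(omega[i, j]))
        return g

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary: fit indices and the strongest edges per network."""
        lines = []
        lines.append("Panel-GVAR results" + (f" [{self.label}]" if self.label else ""))
        lines.append("=" * 64)
        lines.append(f"subjects: {self.nobs}    waves: {self.model.T}    items: {self.model.p}")
        lines.append(f"log-likelihood: {self.llf:.3f}    free parameters: {self.n_free}")
        lines.append(f"BIC: {self.bic:.3f}    AIC: {self.aic:.3f}    converged: {self.converged}")
        edges = self.edge_table()
        for net in ("temporal", "contemporaneous", "between"):
            sub = edges[edges.network == net]
            sub = sub.loc[sub.weight.abs().sort_values(ascending=False).index].head(5)
            lines.append("-" * 64)
            lines.append(f"{net} network: strongest edges")
            for _, r in sub.iterrows():
                arrow = "->" if net == "temporal" else "--"
                se_txt = f" se={r.se:.4f} z={r.z:.2f}" if np.isfinite(r.se) else ""
                lines.append(f"  {r['from']} {arrow} {r['to']}: {r.weight:+.4f}{se_txt}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "loglik": self.llf,
            "deviance": self.deviance,
            "bic": self.bic,
            "n_free": self.n_free,
            "n_subjects": self.nobs,
            "converged": self.converged,
            "mu": self.params.mu.tolist(),
            "temporal": self.params.beta.tolist(),
            "contemporaneous_omega": self.params.contemporaneous.omega.tolist(),
            "contemporaneous_delta": self.params.contemporaneous.delta.tolist(),
            "between_omega": self.params.between.omega.tolist(),
            "between_delta": self.params.between.delta.tolist(),
        }
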