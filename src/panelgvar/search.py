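"""Model-selection workflow: saturated fit -> prune -> step-up -> BIC choice.

Pruning fixes every free edge whose two-sided Wald p-value is at or above the
significance threshold to zero in one simultaneous pass and refits. Step-up
then repeatedly scores each zero-fixed edge by the exact likelihood-ratio
improvement from freeing it alone (a one-at-a-time warm-started refit) and
permanently frees the best candidate while its LRT p-value is below the
threshold and the BIC improves. The best of {saturated, pruned, stepped-up}
by BIC is reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .model import PanelGVARResults
from .params import ParamMasks

__all__ = ["SearchTrace", "prune", "stepup", "select_best", "run_search"]

#: candidate ordering used for tie-breaks
_NETWORK_ORDER = ("temporal", "contemporaneous", "between")


@dataclass
class SearchTrace:
    """Ordered record of search actions and the candidate models."""

    steps: list[dict] = field(default_factory=list)
    candidates: dict[str, PanelGVARResults] = field(default_factory=dict)
    selected: str | None = None

    def log(self, action: str, network: str, edge: tuple[int, int], statistic: float, p_value: float, bic_after: float) -> None:
        self.steps.append(
            {
                "action": action,
                "network": network,
                "edge": [int(edge[0]), int(edge[1])],
                "statistic": float(statistic),
                "p_value": float(p_value),
                "bic_after": float(bic_after),
            }
        )

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.steps:
                fh.write(json.dumps(s) + "\n")
            if self.selected is not None:
                fh.write(json.dumps({"action": "select", "selected": self.selected}) + "\n")


def _edge_entries(masks: ParamMasks, free: bool):
    """Yield (network, (row, col)) for free (or fixed-zero) edge positions.

    Temporal entries include the autoregressive diagonal; GGM entries are
    upper-triangle pairs. Order: temporal row-major, then contemporaneous,
    then between (the tie-break order).
    """
    p = masks.p
    for j in range(p):
        for i in range(p):
            if masks.beta[j, i] == free:
                yield "temporal", (j, i)
    for name, m in (("contemporaneous", masks.omega_zeta), ("between", masks.omega_between)):
        for i in range(p):
            for j in range(i + 1, p):
                if m[i, j] == free:
                    yield name, (i, j)


def _set_edge(masks: ParamMasks, network: str, edge: tuple[int, int], value: bool) -> ParamMasks:
    out = masks.copy()
    if network == "temporal":
        out.beta[edge] = value
    elif network == "contemporaneous":
        out.omega_zeta[edge] = out.omega_zeta[edge[::-1]] = value
    elif network == "between":
        out.omega_between[edge] = out.omega_between[edge[::-1]] = value
    else:
        raise ValueError(f"unknown network {network!r}")
    return out


def prune(fit: PanelGVARResults, alpha: float = 0.05, trace: SearchTrace | None = None) -> PanelGVARResults:
    """Fix all non-significant free edges (Wald p >= alpha) to zero and refit.

    Means and delta scalings are never pruned; autoregressive diagonal
    coefficients are prunable like any other edge. Pruning is a single
    simultaneous pass.
    """
    if not fit.converged:
        raise ValueError("cannot prune a non-converged fit")
    if not fit.se_available:
        raise ValueError("standard errors unavailable; cannot prune")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    se = fit.se
    masks = fit.params.masks.copy()
    p_mat = {
        "temporal": _wald_p(fit.params.beta, se.beta),
        "contemporaneous": _wald_p(fit.params.contemporaneous.omega, se.contemporaneous.omega),
        "between": _wald_p(fit.params.between.omega, se.between.omega),
    }
    n_fixed = 0
    for network, edge in list(_edge_entries(fit.params.masks, free=True)):
        pv = p_mat[network][edge]
        if not np.isfinite(pv) or pv >= alpha:
            masks = _set_edge(masks, network, edge, False)
            n_fixed += 1
            if trace is not None:
                trace.log("prune", network, edge, 0.0, float(pv), np.nan)
    if n_fixed == 0:
        out = _relabel(fit, "pruned")
        return out
    refit = fit.model.fit(masks=masks, start=fit.params, options=fit.options)
    refit.label = "pruned"
    if not refit.converged:
        raise RuntimeError("pruned model failed to converge; model may be non-identified after pruning")
    if trace is not None:
        for s in trace.steps[-n_fixed:]:
            s["bic_after"] = refit.bic
    return refit


def _wald_p(est: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    return 2 * stats.norm.sf(np.abs(z))


def _relabel(fit: PanelGVARResults, label: str) -> PanelGVARResults:
    out = PanelGVARResults(
        model=fit.model,
        params=fit.params,
        deviance=fit.deviance,
        converged=fit.converged,
        optimizer_message=fit.optimizer_message,
        options=fit.options,
        label=label,
    )
    out._se_cache = fit._se_cache
    return out


def stepup(
    fit: PanelGVARResults,
    alpha: float = 0.05,
    max_steps: int | None = None,
    trace: SearchTrace | None = None,
) -> tuple[PanelGVARResults, SearchTrace]:
    """Iteratively free the zero-fixed edge with the best significant LRT.

    At each step every fixed edge is refitted one-at-a-time (warm start from
    the current estimates); the edge with the largest LRT statistic is freed
    permanently if its chi-square(1) p-value is below ``alpha`` AND the BIC
    decreases. Ties break by LRT, then network order (temporal,
    contemporaneous, between), then row-major edge order.
    """
    trace = trace or SearchTrace()
    current = _relabel(fit, "stepup")
    if max_steps is None:
        max_steps = current.model.p**2 * 3
    for _ in range(max_steps):
        fixed = list(_edge_entries(current.params.masks, free=False))
        if not fixed:
            break
        best = None
        for network, edge in fixed:
            masks_try = _set_edge(current.params.masks, network, edge, True)
            try:
                cand = current.model.fit(masks=masks_try, start=current.params, options=current.options)
            except Exception as exc:  # candidate refit failure: skip, log
                warnings.warn(f"step-up candidate {network} {edge} failed: {exc}", stacklevel=2)
                continue
            if not cand.converged:
                continue
            lrt = max(0.0, current.deviance - cand.deviance)
            if best is None or lrt > best[0] + 1e-12:
                best = (lrt, network, edge, cand)
        if best is None:
            break
        lrt, network, edge, cand = best
        p_val = float(stats.chi2.sf(lrt, df=1))
        if p_val >= alpha or cand.bic >= current.bic:
            break
        cand.label = "stepup"
        trace.log("add", network, edge, lrt, p_val, cand.bic)
        current = cand
    return current, trace


def select_best(candidates: list[PanelGVARResults]) -> tuple[str, PanelGVARResults]:
    """Minimal-BIC candidate; ties -> fewer free parameters -> earlier stage."""
    conv = [(i, c) for i, c in enumerate(candidates) if c.converged]
    if not conv:
        raise ValueError("no converged candidate")
    best_i, best = min(conv, key=lambda ic: (round(ic[1].bic, 9), ic[1].n_free, ic[0]))
    return best.label or f"candidate{best_i}", best


def run_search(model, alpha: float = 0.05, options=None, max_steps: int | None = None) -> tuple[PanelGVARResults, SearchTrace]:
    """Full pipeline: saturated -> pruned -> step-up; returns best by BIC."""
    trace = SearchTrace()
    saturated = model.fit(options=options)
    saturated.label = "saturated"
    trace.candidates["saturated"] = saturated
    pruned = prune(saturated, alpha=alpha, trace=trace)
    trace.candidates["pruned"] = pruned
    stepped, trace = stepup(pruned, alpha=alpha, max_steps=max_steps, trace=trace)
    trace.candidates["stepup"] = stepped
    label, best = select_best([saturated, pruned, stepped])
    trace.selected = label
    return best, trace
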