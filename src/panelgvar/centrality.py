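"""Expected-influence centrality for symptom networks.

Expected influence (EI) of a node in an undirected partial-correlation
network is the signed sum of its edge weights, so strong negative edges
reduce rather than inflate a node's standing. In the directed temporal
network the analogues are out-EI (the summed weight of a node's outgoing
lag-1 edges: how strongly a symptom predicts others) and in-EI (summed
incoming edges: how strongly it is predicted by others); autoregressive
self-loops are excluded from both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CentralityTable",
    "expected_influence",
    "in_out_expected_influence",
    "rank_values",
    "centrality_tables",
    "rank_and_report",
]


def expected_influence(weights: np.ndarray) -> np.ndarray:
    """Signed one-step EI per node of an undirected weighted network."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T):
        raise ValueError("undirected network requires a symmetric matrix")
    if np.any(np.diag(w) != 0):
        raise ValueError("self-loops undefined for an undirected GGM (nonzero diagonal)")
    return w.sum(axis=1)


def in_out_expected_influence(temporal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(in-EI, out-EI) per node of the lag-1 matrix ``b[j, i] = i -> j``.

    Autoregressive (diagonal) coefficients are excluded: in-EI_j sums the
    incoming cross-lagged weights b[j, i], i != j; out-EI_i the outgoing ones.
    """
    b = np.asarray(temporal, dtype=float)
    if b.ndim != 2 or b.shape[0] != b.shape[1]:
        raise ValueError("temporal matrix must be square")
    if not np.all(np.isfinite(b)):
        raise ValueError("temporal matrix must be finite")
    off = b - np.diag(np.diag(b))
    in_ei = off.sum(axis=1)   # row sums: incoming edges of node j
    out_ei = off.sum(axis=0)  # column sums: outgoing edges of node i
    return in_ei, out_ei


def rank_values(values: np.ndarray) -> np.ndarray:
    """Ranks with 1 = largest; ties share the minimum rank."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(-v, kind="stable")
    ranks = np.empty(len(v), dtype=int)
    pos = 1
    for idx, i in enumerate(order):
        if idx > 0 and v[i] == v[order[idx - 1]]:
            ranks[i] = ranks[order[idx - 1]]
        else:
            ranks[i] = pos
        pos += 1
    return ranks


@dataclass
class CentralityTable:
    """Per-node centrality values and ranks for one network."""

    network: str
    table: pd.DataFrame  # columns: node, metric, value, rank

    def top(self, metric: str) -> pd.Series:
        sub = self.table[self.table.metric == metric]
        return sub.loc[sub["value"].idxmax()]


def _make_table(network: str, nodes, metrics: dict[str, np.ndarray]) -> CentralityTable:
    rows = []
    for metric, vals in metrics.items():
        ranks = rank_values(vals)
        for node, v, r in zip(nodes, vals, ranks):
            rows.append({"node": node, "metric": metric, "value": float(v), "rank": int(r)})
    return CentralityTable(network=network, table=pd.DataFrame(rows))


def centrality_tables(results) -> dict[str, CentralityTable]:
    """EI tables for the three networks of a fitted panel-GVAR."""
    nodes = results.model.item_names
    in_ei, out_ei = in_out_expected_influence(results.temporal_network)
    return {
        "temporal": _make_table("temporal", nodes, {"in_ei": in_ei, "out_ei": out_ei}),
        "contemporaneous": _make_table("contemporaneous", nodes, {"ei": expected_influence(results.contemporaneous_network)}),
        "between": _make_table("between", nodes, {"ei": expected_influence(results.between_network)}),
    }


def _strongest_edge(network: str, weights: np.ndarray, nodes) -> dict | None:
    w = np.asarray(weights, dtype=float)
    if network == "temporal":
        mask = ~np.eye(w.shape[0], dtype=bool)
        if not np.any(w[mask] != 0):
            return None
        absw = np.where(mask, np.abs(w), -np.inf)
        j, i = np.unravel_index(np.argmax(absw), w.shape)
        return {"from": nodes[i], "to": nodes[j], "weight": float(w[j, i])}
    iu = np.triu_indices(w.shape[0], k=1)
    if not np.any(w[iu] != 0):
        return None
    k = int(np.argmax(np.abs(w[iu])))
    i, j = iu[0][k], iu[1][k]
    return {"from": nodes[i], "to": nodes[j], "weight": float(w[i, j])}


def rank_and_report(results) -> dict:
    """Per-network report: strongest edge, top node per metric, full tables."""
    tables = centrality_tables(results)
    nets = {
        "temporal": results.temporal_network,
        "contemporaneous": results.contemporaneous_network,
        "between": results.between_network,
    }
    report: dict = {}
    for name, tab in tables.items():
        strongest = _strongest_edge(name, nets[name], results.model.item_names)
        top_nodes = {}
        for metric in tab.table.metric.unique():
            sub = tab.table[tab.table.metric == metric]
            if (sub["value"] == 0).all():
                top_nodes[metric] = None
            else:
                best = sub.loc[sub["value"].idxmax()]
                top_nodes[metric] = {"node": best.node, "value": float(best["value"])}
        report[name] = {
            "strongest_edge": strongest,
            "top_nodes": top_nodes,
            "table": tab.table.sort_values(["metric", "rank"], kind="stable").reset_index(drop=True),
        }
    return report
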