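"""Network structure assembly from per-node sensitivity totals.

Every measured node in turn serves as the output of one HDMR mapping with the
remaining nodes as inputs (N nodes -> N mappings per condition).  The edge
weight from input i to output o is the total sensitivity T_i of that mapping,
aggregated across experimental conditions by taking the maximum; connections
whose aggregated weight falls above a threshold tau are called significant.
Pairwise-comparison mappings (Boolean perturbation output) contribute only
edges incident to the perturbed node, which is their output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import DataTable
from .model_fit import FitConfig, HDMRModel, fit_hdmr
from .sensitivity import SensitivityReport, compute_sensitivities

logger = logging.getLogger("hdmrnet")

__all__ = [
    "NetworkGraph",
    "fit_all_nodes",
    "aggregate_network",
    "threshold_network",
    "export_network",
    "edge_threshold_profile",
]


@dataclass
class NetworkGraph:
    """Directed sensitivity-weighted graph: W[output, input] with threshold tau.

    The weight matrix follows the convention rows = outputs, columns = inputs;
    the diagonal is undefined (a node is never its own input) and stored as
    NaN.  ``provenance`` records, per (output, input), the condition whose
    report achieved the maximum.
    """

    nodes: list[str]
    weights: pd.DataFrame  # index = outputs, columns = inputs
    tau: float = 0.1
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Significant connections as (input, output) pairs: W >= tau."""
        out = set()
        W = self.weights
        for o in self.nodes:
            for i in self.nodes:
                if i == o:
                    continue
                w = W.loc[o, i]
                if np.isfinite(w) and w >= self.tau:
                    out.add((i, o))
        return out

    def normalized_weights(self) -> pd.DataFrame:
        """Weights rescaled so the largest entry is 1 (cross-method comparison)."""
        m = np.nanmax(self.weights.to_numpy())
        return self.weights / m if m > 0 else self.weights.copy()

    def symmetrized(self) -> pd.DataFrame:
        """max(W[o,i], W[i,o]) view for comparison with undirected methods."""
        W = self.weights.to_numpy()
        return pd.DataFrame(
            np.fmax(W, W.T), index=self.weights.index, columns=self.weights.columns
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for i, o in self.edges:
            g.add_edge(
                i,
                o,
                weight=float(self.weights.loc[o, i]),
                condition=self.provenance.get((o, i), ""),
            )
        return g


def fit_all_nodes(
    table: DataTable, config: FitConfig | None = None
) -> list[tuple[HDMRModel | None, SensitivityReport | None]]:
    """One HDMR mapping per node: each node as output, the rest as inputs.

    A node whose fit fails is recorded (model = report = None) and logged, not
    fatal — the remaining mappings still define most of the network.
    """
    if table.n_nodes < 2:
        raise ValueError("need at least 2 nodes to form input-output mappings")
    out = []
    for node in table.node_names:
        try:
            model = fit_hdmr(table, node, config)
            report = compute_sensitivities(model, table)
            out.append((model, report))
        except Exception as exc:
            logger.warning(
                "condition %r: fit for output %r failed: %s",
                table.condition_id,
                node,
                exc,
            )
            out.append((None, None))
    return out


def aggregate_network(
    reports: dict[str, list[SensitivityReport]],
    pairwise_reports: dict[str, list[SensitivityReport]] | None = None,
    tau: float = 0.1,
    nodes: list[str] | None = None,
) -> NetworkGraph:
    """Max-over-conditions aggregation of total sensitivity indices.

    ``reports`` maps condition id -> list of per-output reports for that
    condition.  W[out, in] = max over conditions of T_in from the report whose
    output is ``out``.  Pairwise-comparison reports (keyed by condition id in
    ``pairwise_reports``) enter the same maximum but only for the row of their
    own output — the perturbed node — so they contribute only edges incident
    to the perturbed species.
    """
    all_reports = [(cid, r) for cid, rs in reports.items() for r in rs if r is not None]
    if pairwise_reports:
        all_reports += [
            (cid, r)
            for cid, rs in pairwise_reports.items()
            for r in rs
            if r is not None
        ]
    if not all_reports:
        raise ValueError("no sensitivity reports to aggregate")

    if nodes is None:
        universe: set[str] = set()
        for _cid, r in all_reports:
            universe.add(r.output_id)
            universe.update(r.T.keys())
        nodes = sorted(universe)
    else:
        for _cid, r in all_reports:
            extra = ({r.output_id} | set(r.T)) - set(nodes)
            if extra:
                raise ValueError(f"report for {r.output_id!r} names unknown nodes {extra}")

    W = pd.DataFrame(np.nan, index=nodes, columns=nodes, dtype=float)
    provenance: dict[tuple[str, str], str] = {}
    for cid, r in all_reports:
        o = r.output_id
        for i, t in r.T.items():
            if i == o:
                continue
            cur = W.loc[o, i]
            if not np.isfinite(cur) or t > cur:
                W.loc[o, i] = t
                provenance[(o, i)] = cid
    # an input absent from every report's T was tested and contributed no
    # significant component -> weight 0, not missing
    offdiag = ~np.eye(len(nodes), dtype=bool)
    Wv = W.to_numpy().copy()
    Wv[offdiag & ~np.isfinite(Wv)] = 0.0
    np.fill_diagonal(Wv, np.nan)
    W = pd.DataFrame(Wv, index=nodes, columns=nodes)
    return NetworkGraph(nodes=list(nodes), weights=W, tau=tau, provenance=provenance)


def threshold_network(graph: NetworkGraph, tau: float) -> NetworkGraph:
    """Same weights, new significance threshold (edges follow W >= tau)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return replace(graph, weights=graph.weights.copy(), tau=tau)


def edge_threshold_profile(
    graph: NetworkGraph, taus: np.ndarray | None = None
) -> pd.DataFrame:
    """Edge count as a function of tau, for empirical threshold choice."""
    W = graph.weights.to_numpy()
    vals = W[np.isfinite(W)]
    if taus is None:
        taus = np.unique(np.round(np.concatenate([[0.0], vals]), 6))
    return pd.DataFrame(
        {"tau": taus, "n_edges": [int(np.sum(vals >= t)) for t in taus]}
    )


def export_network(
    graph: NetworkGraph, path, format: str = "adjacency-tsv", normalized: bool = False
) -> None:
    """Write the network as an adjacency TSV, a SIF edge list, or JSON.

    adjacency-tsv: full W matrix with node headers (rows = outputs).
    edge-list-sif: one line "input<TAB>hdmr<TAB>output" per significant edge.
    json: weights, tau, edges and per-edge condition provenance.
    """
    W = graph.normalized_weights() if normalized else graph.weights
    if format == "adjacency-tsv":
        W.to_csv(path, sep="\t", index=True, index_label="output\\input")
    elif format == "edge-list-sif":
        with open(path, "w") as fh:
            for i, o in sorted(graph.edges):
                fh.write(f"{i}\thdmr\t{o}\n")
    elif format == "json":
        doc = {
            "nodes": graph.nodes,
            "tau": graph.tau,
            "weights": {
                o: {
                    i: (None if not np.isfinite(W.loc[o, i]) else float(W.loc[o, i]))
                    for i in graph.nodes
                }
                for o in graph.nodes
            },
            "edges": [[i, o] for i, o in sorted(graph.edges)],
            "provenance": {f"{o}<-{i}": c for (o, i), c in graph.provenance.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_adjacency(path) -> pd.DataFrame:
    """Read back an adjacency TSV written by :func:`export_network`."""
    return pd.read_csv(path, sep="\t", index_col=0)
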