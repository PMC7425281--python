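"""Structural network metrics and ground-truth vs inferred comparison.

All metrics operate on the unweighted (binarized) graph.  The battery
mirrors what classroom social-network studies report: density, Newman's
gender assortativity, Freeman (in-)degree and closeness centralization,
plus node-level degree and eigenvector centrality.

Centralization is normalized so that a star graph scores exactly 1 and
a clique 0:

    C = sum_v (c_max - c_v) / H

with H the star's attainable sum for a graph of the same size —
(n-1)(n-2) for undirected degree, (n-1)^2 for in-degree on directed
graphs, and (n-1)(n-2)/(2n-3) for closeness (on the Wasserman–Faust
scaled closeness, which stays defined on disconnected graphs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
from scipy import stats

__all__ = [
    "SNAReport",
    "density",
    "assortativity_gender",
    "centralization",
    "node_centrality",
    "build_report",
    "compare",
]

NodeId = Hashable


def density(net: nx.Graph | nx.DiGraph) -> float:
    """Edges over possible edges; isolates count toward the node total."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    e = net.number_of_edges()
    possible = n * (n - 1) if net.is_directed() else n * (n - 1) // 2
    return e / possible


def assortativity_gender(
    net: nx.Graph | nx.DiGraph, gender: Mapping[NodeId, str] | None = None
) -> float:
    """Newman's discrete assortativity coefficient on gender labels.

    r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i) over the
    edge-end mixing matrix; +1 when every edge joins same-gender nodes,
    -1 for a perfectly heterophilous (bipartite-by-gender) graph.
    Returns NaN when the graph has no edges or the connected nodes all
    share one gender (the coefficient is undefined, not 1).
    """
    if gender is not None:
        net = net.copy()
        nx.set_node_attributes(net, dict(gender), "gender")
    if net.number_of_edges() == 0:
        return float("nan")
    endpoint_labels = set()
    for u, v in net.edges():
        for node in (u, v):
            g = net.nodes[node].get("gender")
            if g is None:
                raise ValueError(f"node {node!r} has an edge but no gender label")
            endpoint_labels.add(g)
    if len(endpoint_labels) < 2:
        return float("nan")
    return float(nx.attribute_assortativity_coefficient(net, "gender"))


def _closeness(net: nx.Graph | nx.DiGraph) -> dict:
    # Wasserman–Faust scaling keeps closeness meaningful with isolates:
    # within-component closeness is scaled by (reachable-1)/(n-1).
    return nx.closeness_centrality(net, wf_improved=True)


def centralization(net: nx.Graph | nx.DiGraph, kind: str = "degree") -> float:
    """Freeman graph centralization for degree, in-degree or closeness."""
    n = net.number_of_nodes()
    if n < 3:
        raise ValueError("centralization requires at least 3 nodes")
    if kind == "degree":
        if net.is_directed():
            raise ValueError("plain degree centralization is for undirected graphs")
        c = dict(net.degree())
        h = (n - 1) * (n - 2)
    elif kind == "in_degree":
        if not net.is_directed():
            raise ValueError("in-degree centralization is for directed graphs")
        c = dict(net.in_degree())
        h = (n - 1) ** 2
    elif kind == "closeness":
        c = _closeness(net)
        h = (n - 1) * (n - 2) / (2 * n - 3)
    else:
        raise ValueError(f"unknown centralization kind {kind!r}")
    cmax = max(c.values())
    return sum(cmax - v for v in c.values()) / h


def node_centrality(net: nx.Graph | nx.DiGraph, kind: str = "degree") -> dict:
    """Per-node centrality: integer tie counts or eigenvector scores.

    Degree kinds return raw tie counts (the individual-level measure as
    reported in classroom studies).  Eigenvector centrality is computed
    by power iteration (tol 1e-9, up to 10000 iterations) and rescaled
    so the most central node scores 1.
    """
    if kind == "degree":
        return dict(net.degree())
    if kind == "in_degree":
        if not net.is_directed():
            raise ValueError("in-degree centrality requires a directed graph")
        return dict(net.in_degree())
    if kind == "eigenvector":
        if net.number_of_edges() == 0:
            raise ValueError("eigenvector centrality requires at least one edge")
        scores = nx.eigenvector_centrality(net, max_iter=10000, tol=1e-9)
        top = max(scores.values())
        return {k: v / top for k, v in scores.items()}
    raise ValueError(f"unknown centrality kind {kind!r}")


@dataclass
class SNAReport:
    """The structural metric battery for one network."""

    n_nodes: int
    pct_female: float
    density: float
    assortativity_gender: float
    centralization_degree: float  # in-degree on directed graphs
    centralization_closeness: float
    degree_centrality: dict = field(default_factory=dict)
    eigenvector_centrality: dict = field(default_factory=dict)
    directed: bool = False

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "pct_female": self.pct_female,
            "density": self.density,
            "assortativity_gender": self.assortativity_gender,
            "centralization_degree": self.centralization_degree,
            "centralization_closeness": self.centralization_closeness,
            "directed": self.directed,
            "degree_centrality": dict(self.degree_centrality),
            "eigenvector_centrality": dict(self.eigenvector_centrality),
        }


def build_report(
    net: nx.Graph | nx.DiGraph,
    gender: Mapping[NodeId, str] | None = None,
    female_label: str = "F",
) -> SNAReport:
    """Compute the full metric battery for one (binarized) network."""
    if gender is None:
        gender = {
            n: d.get("gender") for n, d in net.nodes(data=True) if d.get("gender")
        }
    n = net.number_of_nodes()
    n_female = sum(1 for v in gender.values() if v == female_label)
    directed = net.is_directed()
    deg_kind = "in_degree" if directed else "degree"
    try:
        assort = assortativity_gender(net, gender if gender else None)
    except ValueError:
        assort = float("nan")
    try:
        eig = node_centrality(net, "eigenvector")
    except (ValueError, nx.PowerIterationFailedConvergence):
        eig = {}
    return SNAReport(
        n_nodes=n,
        pct_female=n_female / n if n else float("nan"),
        density=density(net),
        assortativity_gender=assort,
        centralization_degree=centralization(net, deg_kind),
        centralization_closeness=centralization(net, "closeness"),
        degree_centrality=node_centrality(net, deg_kind),
        eigenvector_centrality=eig,
        directed=directed,
    )


def compare(gt_report: SNAReport, bt_report: SNAReport) -> dict:
    """Side-by-side GT/BT metrics with deltas and degree-rank correlation."""
    if set(gt_report.degree_centrality) != set(bt_report.degree_centrality):
        raise ValueError("reports cover different rosters")
    rows = {}
    for name in (
        "density",
        "assortativity_gender",
        "centralization_degree",
        "centralization_closeness",
    ):
        g = getattr(gt_report, name)
        b = getattr(bt_report, name)
        rows[name] = {"gt": g, "bt": b, "delta": b - g}
    nodes = sorted(gt_report.degree_centrality, key=repr)
    gdeg = [gt_report.degree_centrality[n] for n in nodes]
    bdeg = [bt_report.degree_centrality[n] for n in nodes]
    if len(nodes) >= 2 and (len(set(gdeg)) > 1 and len(set(bdeg)) > 1):
        rho = float(stats.spearmanr(gdeg, bdeg).statistic)
    elif gdeg == bdeg:
        rho = 1.0
    else:
        rho = float("nan")
    rows["degree_rank_correlation"] = {"gt": None, "bt": None, "delta": rho}
    return rows
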