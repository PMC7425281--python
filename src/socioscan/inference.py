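"""Bluetooth network construction from a windowed scan log.

The pairwise connection weight is the Laplace-smoothed ratio

    w(i,j) = (num_connections(i,j) + num_connections(j,i) + alpha)
             / (num_scans(i) + num_scans(j) + beta)

where num_connections(i,j) counts the scan periods in which i detected
j and num_scans(i) counts i's successful scan periods (slots in which i
logged at least one detection).  The weight is symmetric by
construction; alpha=0, beta=1 shrink weights toward 0, more strongly
for pairs with little scan activity.  Thresholding at a strict
connection-weight cut then yields the inferred network; roster nodes
that lose all edges remain in the graph as isolates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable

import networkx as nx

from .io import ScanLog

__all__ = [
    "WindowSpec",
    "SmoothingParams",
    "DetectionCounts",
    "window_log",
    "count_detections",
    "edge_weight",
    "pair_weights",
    "build_bt_network",
    "isolated_fraction",
]

NodeId = Hashable


@dataclass(frozen=True)
class WindowSpec:
    """Cumulative prefix window: first ``n_days`` days, first ``n_scans``
    eligible scan periods (both over the log's ordered schedule)."""

    n_days: int
    n_scans: int

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.n_scans < 1:
            raise ValueError("window sizes must be >= 1")


@dataclass(frozen=True)
class SmoothingParams:
    """Laplace smoothing constants (numerator alpha, denominator beta)."""

    alpha: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("smoothing parameters must be non-negative")


@dataclass
class DetectionCounts:
    """Slot-level detection tallies behind the weight formula.

    ``num_connections[(i, j)]`` — distinct (wave, day, period) slots in
    which i detected j; ``num_scans[i]`` — distinct slots in which i
    logged at least one detection.
    """

    num_connections: dict[tuple[NodeId, NodeId], int] = field(default_factory=dict)
    num_scans: dict[NodeId, int] = field(default_factory=dict)

    def connections(self, i: NodeId, j: NodeId) -> int:
        return self.num_connections.get((i, j), 0)

    def scans(self, i: NodeId) -> int:
        return self.num_scans.get(i, 0)


def window_log(log: ScanLog, w: WindowSpec) -> ScanLog:
    """Restrict a log to the first n_days days and n_scans periods."""
    if w.n_days > len(log.days):
        raise ValueError(f"window of {w.n_days} days exceeds schedule ({len(log.days)})")
    if w.n_scans > len(log.periods):
        raise ValueError(
            f"window of {w.n_scans} scan periods exceeds schedule ({len(log.periods)})"
        )
    day_set = set(log.days[: w.n_days])
    period_set = set(log.periods[: w.n_scans])
    kept = [r for r in log.records if r.day in day_set and r.period in period_set]
    return log.replace_records(kept)


def count_detections(log: ScanLog) -> DetectionCounts:
    """Tally num_connections and num_scans over distinct slots."""
    conn_slots: dict[tuple[NodeId, NodeId], set] = {}
    scan_slots: dict[NodeId, set] = {}
    for r in log.records:
        slot = (r.wave, r.day, r.period)
        conn_slots.setdefault((r.scanner, r.detected), set()).add(slot)
        scan_slots.setdefault(r.scanner, set()).add(slot)
    return DetectionCounts(
        num_connections={k: len(v) for k, v in conn_slots.items()},
        num_scans={k: len(v) for k, v in scan_slots.items()},
    )


def edge_weight(
    counts: DetectionCounts, i: NodeId, j: NodeId, s: SmoothingParams = SmoothingParams()
) -> float:
    """Laplace-smoothed symmetric connection weight for the pair (i, j)."""
    if i == j:
        raise ValueError("edge weight undefined for a self-pair")
    num = counts.connections(i, j) + counts.connections(j, i) + s.alpha
    den = counts.scans(i) + counts.scans(j) + s.beta
    if den == 0:
        raise ZeroDivisionError(
            f"weight denominator is 0 for pair ({i!r}, {j!r}): "
            "no scans and beta = 0"
        )
    return num / den


def pair_weights(
    counts: DetectionCounts,
    roster: Iterable[NodeId] | None = None,
    s: SmoothingParams = SmoothingParams(),
) -> dict[frozenset, float]:
    """Weights for every unordered pair with at least one detection.

    Pairs without any detection have weight alpha/(scans+beta); they are
    included only when alpha > 0 and a roster is supplied, since they
    can then clear a positive threshold.
    """
    weights: dict[frozenset, float] = {}
    for (i, j) in counts.num_connections:
        key = frozenset((i, j))
        if key not in weights:
            weights[key] = edge_weight(counts, i, j, s)
    if s.alpha > 0 and roster is not None:
        nodes = list(roster)
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                key = frozenset((nodes[a], nodes[b]))
                if key not in weights:
                    weights[key] = edge_weight(counts, nodes[a], nodes[b], s)
    return weights


def build_bt_network(
    log: ScanLog,
    w: WindowSpec,
    ctype: str = "undirected",
    threshold: float = 0.0,
    s: SmoothingParams = SmoothingParams(),
) -> nx.Graph | nx.DiGraph:
    """Infer the thresholded Bluetooth network from a windowed log.

    Only pairs with weight strictly greater than ``threshold`` become
    edges.  The directed variant carries two opposite arcs with the same
    (symmetric) weight.  All roster nodes are present, isolates included.
    """
    if ctype not in ("directed", "undirected"):
        raise ValueError(f"connection type must be directed|undirected, got {ctype!r}")
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    sub = window_log(log, w)
    counts = count_detections(sub)
    weights = pair_weights(counts, roster=sub.roster, s=s)
    G: nx.Graph | nx.DiGraph = nx.DiGraph() if ctype == "directed" else nx.Graph()
    for node, attrs in log.roster.items():
        G.add_node(node, **attrs)
    for key, wt in weights.items():
        if wt > threshold:
            i, j = tuple(key)
            G.add_edge(i, j, weight=wt)
            if ctype == "directed":
                G.add_edge(j, i, weight=wt)
    G.graph["directed"] = ctype == "directed"
    G.graph["threshold"] = threshold
    G.graph["n_days"] = w.n_days
    G.graph["n_scans"] = w.n_scans
    return G


def isolated_fraction(net: nx.Graph | nx.DiGraph, roster: Iterable[NodeId]) -> float:
    """Fraction of roster nodes with no edges in the network."""
    roster = list(roster)
    if not roster:
        raise ValueError("roster is empty")
    deg = dict(net.degree())
    isolated = sum(1 for n in roster if deg.get(n, 0) == 0)
    return isolated / len(roster)
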