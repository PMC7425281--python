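"""Weighted ground-truth (GT) networks from peer nominations.

Participants nominate classmates on six sociometric items (advice,
friendship, leadership, respect, hanging out, want-to-be-like).  The
directed GT weight from i to j is the number of distinct items on which
i nominated j, divided by 6; the undirected weight pools both directions
and divides by 12.  Weights therefore live in [0, 1] and an edge exists
whenever at least one nomination was given.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Mapping

import networkx as nx

from .io import NominationRecord

__all__ = ["build_gt_directed", "build_gt_undirected", "gt_edge_set"]

NodeId = Hashable

N_ITEMS = 6


def _item_counts(
    noms: Iterable[NominationRecord], roster: set
) -> dict[tuple[NodeId, NodeId], int]:
    """Distinct-item nomination counts per ordered (nominator, nominee).

    Repeated nominations of the same peer on the same item count once:
    each item is a binary single-item measure.
    """
    seen: set[tuple[NodeId, NodeId, int]] = set()
    off_roster = sorted(
        {r.nominator for r in noms if r.nominator not in roster}
        | {r.nominee for r in noms if r.nominee not in roster},
        key=repr,
    )
    if off_roster:
        raise ValueError(f"nomination node ids not on roster: {off_roster}")
    counts: dict[tuple[NodeId, NodeId], int] = {}
    for r in noms:
        key = (r.nominator, r.nominee, r.item)
        if key in seen:
            continue
        seen.add(key)
        pair = (r.nominator, r.nominee)
        counts[pair] = counts.get(pair, 0) + 1
    return counts


def build_gt_directed(
    noms: Iterable[NominationRecord],
    roster: Mapping[NodeId, dict] | Iterable[NodeId],
) -> nx.DiGraph:
    """Directed GT network: edge i→j with weight (#items i named j on)/6."""
    noms = list(noms)
    roster_d = dict(roster) if isinstance(roster, Mapping) else {n: {} for n in roster}
    counts = _item_counts(noms, set(roster_d))
    G = nx.DiGraph(provenance="nominations", directed=True)
    for node, attrs in roster_d.items():
        G.add_node(node, **attrs)
    for (i, j), c in counts.items():
        G.add_edge(i, j, weight=c / N_ITEMS)
    return G


def build_gt_undirected(
    noms: Iterable[NominationRecord],
    roster: Mapping[NodeId, dict] | Iterable[NodeId],
) -> nx.Graph:
    """Undirected GT network: weight (noms i→j + noms j→i)/12.

    An edge exists whenever the pooled nomination count is positive;
    mutuality is not required.
    """
    noms = list(noms)
    roster_d = dict(roster) if isinstance(roster, Mapping) else {n: {} for n in roster}
    counts = _item_counts(noms, set(roster_d))
    G = nx.Graph(provenance="nominations", directed=False)
    for node, attrs in roster_d.items():
        G.add_node(node, **attrs)
    pooled: dict[frozenset, int] = {}
    for (i, j), c in counts.items():
        key = frozenset((i, j))
        pooled[key] = pooled.get(key, 0) + c
    for key, c in pooled.items():
        i, j = tuple(key)
        G.add_edge(i, j, weight=c / (2 * N_ITEMS))
    return G


def gt_edge_set(net: nx.Graph | nx.DiGraph) -> set:
    """Pairs with positive weight: ordered for directed, frozensets otherwise."""
    if net.is_directed():
        return {(u, v) for u, v, w in net.edges(data="weight", default=1.0) if w > 0}
    return {frozenset((u, v)) for u, v, w in net.edges(data="weight", default=1.0) if w > 0}
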