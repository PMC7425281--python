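"""Brute-force network validation: grid search, confusion metrics, selection.

Every combination of connection-weight threshold, cumulative day/scan
window and connection type yields one candidate Bluetooth network.
Each candidate is scored against the ground-truth network by edge-wise
classification over the full pair universe (all ordered pairs for
directed networks, all unordered pairs for undirected), using accuracy
for balanced edge classes or the Matthews correlation coefficient (MCC)
for sparse ones.  The optimal candidate is the accuracy/MCC argmax,
with ties resolved toward fewer Bluetooth observations, then fewer
days, then fewer scan periods, then the lexicographically smallest
parameter tuple so that selection is fully deterministic.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .ground_truth import gt_edge_set
from .inference import SmoothingParams, WindowSpec, count_detections, pair_weights, window_log
from .io import ScanLog

__all__ = [
    "GridSpec",
    "ConfusionCounts",
    "ValidationResult",
    "enumerate_grid",
    "confusion",
    "confusion_from_sets",
    "accuracy",
    "mcc",
    "run_grid",
    "count_distinct",
    "select_optimal",
    "baseline",
    "results_to_frame",
]

NodeId = Hashable


def default_weight_values(maximum: float = 0.60, step: float = 0.01) -> tuple[float, ...]:
    """Threshold grid 0.01, 0.02, ..., maximum (60 values at the defaults).

    0.0 is deliberately excluded: it is the baseline (no thresholding).
    """
    n = round(maximum / step)
    return tuple(round(step * k, 10) for k in range(1, n + 1))


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid for the brute-force search."""

    weight_values: tuple[float, ...]
    day_windows: tuple[int, ...]
    scan_windows: tuple[int, ...]
    connection_types: tuple[str, ...] = ("undirected",)
    metric: str = "accuracy"

    def __post_init__(self) -> None:
        if not self.weight_values or not self.day_windows or not self.scan_windows:
            raise ValueError("grid components must be non-empty")
        if not self.connection_types:
            raise ValueError("at least one connection type required")
        if any(b <= a for a, b in zip(self.weight_values, self.weight_values[1:])):
            raise ValueError("weight values must be strictly increasing")
        if self.metric not in ("accuracy", "mcc"):
            raise ValueError(f"metric must be accuracy|mcc, got {self.metric!r}")
        for ct in self.connection_types:
            if ct not in ("directed", "undirected"):
                raise ValueError(f"bad connection type {ct!r}")

    @classmethod
    def default(
        cls,
        n_days: int,
        n_scans: int,
        connection_types: Sequence[str] = ("undirected",),
        metric: str = "accuracy",
        weight_max: float = 0.60,
        weight_step: float = 0.01,
    ) -> "GridSpec":
        """Standard grid: thresholds 0.01..weight_max, all day/scan prefixes."""
        return cls(
            weight_values=default_weight_values(weight_max, weight_step),
            day_windows=tuple(range(1, n_days + 1)),
            scan_windows=tuple(range(1, n_scans + 1)),
            connection_types=tuple(connection_types),
            metric=metric,
        )


@dataclass(frozen=True)
class ConfusionCounts:
    """Edge-classification confusion counts over the full pair universe."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ValidationResult:
    """One grid point: parameters, confusion counts, metric, provenance."""

    weight: float
    n_days: int
    n_scans: int
    ctype: str
    confusion: ConfusionCounts
    metric: str
    metric_value: float
    n_bt_observations: int
    fingerprint: str

    @property
    def params(self) -> tuple:
        return (self.weight, self.n_days, self.n_scans, self.ctype)


def enumerate_grid(spec: GridSpec) -> list[tuple[str, float, int, int]]:
    """All (ctype, weight, n_days, n_scans) tuples in lexicographic order."""
    return [
        (ct, w, nd, ns)
        for ct in spec.connection_types
        for w in spec.weight_values
        for nd in spec.day_windows
        for ns in spec.scan_windows
    ]


def _universe_size(n: int, directed: bool) -> int:
    return n * (n - 1) if directed else n * (n - 1) // 2


def confusion_from_sets(
    bt_edges: set, gt_edges: set, roster: Sequence[NodeId], directed: bool
) -> ConfusionCounts:
    """Confusion counts from raw edge sets over the roster pair universe."""
    total = _universe_size(len(roster), directed)
    tp = len(bt_edges & gt_edges)
    fp = len(bt_edges - gt_edges)
    fn = len(gt_edges - bt_edges)
    tn = total - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def confusion(
    bt: nx.Graph | nx.DiGraph,
    gt: nx.Graph | nx.DiGraph,
    roster: Iterable[NodeId],
) -> ConfusionCounts:
    """Edge-presence confusion counts between inferred and GT networks."""
    if bt.is_directed() != gt.is_directed():
        raise ValueError("inferred and ground-truth networks differ in directedness")
    roster = list(roster)
    roster_set = set(roster)
    directed = bt.is_directed()

    def edge_set(net):
        if directed:
            return {
                (u, v) for u, v in net.edges() if u in roster_set and v in roster_set
            }
        return {
            frozenset((u, v))
            for u, v in net.edges()
            if u in roster_set and v in roster_set
        }

    return confusion_from_sets(edge_set(bt), edge_set(gt), roster, directed)


def accuracy(c: ConfusionCounts) -> float:
    """Fraction of pairs whose edge/non-edge status matches the GT."""
    if c.total == 0:
        raise ValueError("empty pair universe")
    return (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), ranging
    from -1 (perfect misclassification) to +1 (perfect classification);
    0 corresponds to a coin-tossing classifier.  The zero-denominator
    convention (return 0) keeps degenerate predictions comparable.
    """
    denom = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


_METRICS = {"accuracy": accuracy, "mcc": mcc}


def _fingerprint(edges: Iterable, directed: bool) -> str:
    """Canonical hash of an edge set (direction-aware for directed nets)."""
    if directed:
        canon = sorted((repr(u), repr(v)) for u, v in edges)
    else:
        canon = sorted(tuple(sorted((repr(a) for a in e))) for e in edges)
    h = hashlib.sha1(repr(canon).encode()).hexdigest()
    return h[:16]


def _gt_for_ctype(gt, ctype: str):
    if isinstance(gt, Mapping):
        try:
            return gt[ctype]
        except KeyError:
            raise ValueError(f"no ground-truth network supplied for {ctype!r}") from None
    if gt.is_directed() != (ctype == "directed"):
        raise ValueError(
            f"ground-truth directedness does not match connection type {ctype!r}"
        )
    return gt


def run_grid(
    log: ScanLog,
    gt,
    spec: GridSpec,
    s: SmoothingParams = SmoothingParams(),
) -> list[ValidationResult]:
    """Evaluate every grid point, one :class:`ValidationResult` each.

    ``gt`` is a single GT network (when one connection type is searched)
    or a mapping {'directed': ..., 'undirected': ...}.  Within a window
    the pair weights are computed once and re-thresholded per weight
    value, which is equivalent to rebuilding each network from scratch.
    """
    roster = sorted(log.roster, key=repr)
    results: list[ValidationResult] = []
    # Precompute per-window weights and observation counts.
    window_cache: dict[tuple[int, int], tuple[dict, int]] = {}
    for nd in spec.day_windows:
        for ns in spec.scan_windows:
            sub = window_log(log, WindowSpec(nd, ns))
            counts = count_detections(sub)
            window_cache[(nd, ns)] = (pair_weights(counts, roster=roster, s=s), len(sub))
    gt_sets = {}
    for ct in spec.connection_types:
        gt_sets[ct] = gt_edge_set(_gt_for_ctype(gt, ct))
    metric_fn = _METRICS[spec.metric]
    for ct, w, nd, ns in enumerate_grid(spec):
        weights, n_obs = window_cache[(nd, ns)]
        pairs = {key for key, wt in weights.items() if wt > w}
        if ct == "directed":
            bt_edges = set()
            for key in pairs:
                i, j = tuple(key)
                bt_edges.add((i, j))
                bt_edges.add((j, i))
        else:
            bt_edges = pairs
        c = confusion_from_sets(bt_edges, gt_sets[ct], roster, ct == "directed")
        results.append(
            ValidationResult(
                weight=w,
                n_days=nd,
                n_scans=ns,
                ctype=ct,
                confusion=c,
                metric=spec.metric,
                metric_value=metric_fn(c),
                n_bt_observations=n_obs,
                fingerprint=_fingerprint(bt_edges, ct == "directed"),
            )
        )
    return results


def count_distinct(
    results: Sequence[ValidationResult], decimals: int = 4
) -> tuple[int, int]:
    """(#distinct metric values rounded to ``decimals``, #distinct networks)."""
    if not results:
        raise ValueError("no results")
    values = {round(r.metric_value, decimals) for r in results}
    nets = {r.fingerprint for r in results}
    return len(values), len(nets)


def select_optimal(
    results: Sequence[ValidationResult],
) -> tuple[ValidationResult, dict]:
    """Pick the optimal candidate and report the tie-breaking trace.

    Ranking: max metric value; then min Bluetooth observations used;
    then min days; then min scan periods; a final lexicographic
    comparison of the parameter tuple guarantees a unique winner.
    """
    if not results:
        raise ValueError("no results to select from")
    best_metric = max(r.metric_value for r in results)
    stage1 = [r for r in results if r.metric_value == best_metric]
    min_obs = min(r.n_bt_observations for r in stage1)
    stage2 = [r for r in stage1 if r.n_bt_observations == min_obs]
    min_days = min(r.n_days for r in stage2)
    stage3 = [r for r in stage2 if r.n_days == min_days]
    min_scans = min(r.n_scans for r in stage3)
    stage4 = [r for r in stage3 if r.n_scans == min_scans]
    winner = min(stage4, key=lambda r: r.params)
    trace = {
        "metric": winner.metric,
        "best_metric_value": best_metric,
        "n_at_best_metric": len(stage1),
        "n_after_obs_tiebreak": len(stage2),
        "n_after_day_tiebreak": len(stage3),
        "n_after_scan_tiebreak": len(stage4),
        "winner_params": {
            "weight": winner.weight,
            "n_days": winner.n_days,
            "n_scans": winner.n_scans,
            "ctype": winner.ctype,
        },
    }
    return winner, trace


def baseline(
    log: ScanLog,
    gt,
    ctype: str = "undirected",
    s: SmoothingParams = SmoothingParams(),
    metric: str = "accuracy",
) -> ValidationResult:
    """No-optimization scenario: threshold 0, maximal day/scan window."""
    spec = GridSpec(
        weight_values=(0.0,),
        day_windows=(len(log.days),),
        scan_windows=(len(log.periods),),
        connection_types=(ctype,),
        metric=metric,
    )
    return run_grid(log, gt, spec, s)[0]


def results_to_frame(results: Sequence[ValidationResult]) -> pd.DataFrame:
    """Results as a flat table, one row per grid tuple."""
    rows = [
        {
            "weight": r.weight,
            "n_days": r.n_days,
            "n_scans": r.n_scans,
            "ctype": r.ctype,
            "tp": r.confusion.tp,
            "tn": r.confusion.tn,
            "fp": r.confusion.fp,
            "fn": r.confusion.fn,
            "metric": r.metric,
            "metric_value": r.metric_value,
            "n_bt_observations": r.n_bt_observations,
            "fingerprint": r.fingerprint,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
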