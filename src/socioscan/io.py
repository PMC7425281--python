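"""Readers, writers and data-quality filters for proximity scan data.

The on-disk formats are plain CSV: a scan log (one row per Bluetooth
detection event, schema configurable through a column-name *dialect*),
a peer-nomination table, a binary friendship adjacency matrix, and the
usual network export formats (edge-list CSV and GraphML).

All analysis operates on within-class rosters: detections of devices
that are not on the roster are excluded rather than added as nodes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "FormatError",
    "ScanRecord",
    "ScanLog",
    "NominationRecord",
    "DEFAULT_DIALECT",
    "read_scan_log",
    "read_roster",
    "read_nominations",
    "write_nominations",
    "read_friendship_matrix",
    "filter_participation",
    "filter_scan_periods",
    "write_network",
    "read_network",
    "write_scan_log",
]

NodeId = Hashable


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


#: Default column mapping: logical field -> CSV header name.  Matches the
#: schema "School, Class, Wave, Day, Date, Time, Child_ID, Detected_Child_ID"
#: used by school-class proximity studies; ``period`` carries the scan-slot
#: label (S0, S1, ...).
DEFAULT_DIALECT: dict[str, str] = {
    "scanner": "Child_ID",
    "detected": "Detected_Child_ID",
    "wave": "Wave",
    "day": "Day",
    "period": "Scan_Period",
}


@dataclass(frozen=True, order=True)
class ScanRecord:
    """One deduplicated detection: ``scanner`` saw ``detected`` in a slot."""

    scanner: NodeId
    detected: NodeId
    wave: str
    day: int  # 1-based ordinal day index
    period: int  # 0-based ordinal scan-period index

    def __post_init__(self) -> None:
        if self.scanner == self.detected:
            raise ValueError(f"self-detection for node {self.scanner!r}")
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        if self.period < 0:
            raise ValueError(f"scan period must be >= 0, got {self.period}")


@dataclass
class ScanLog:
    """A deduplicated scan log plus roster and scan schedule.

    ``days`` and ``periods`` are the ordered lists of day indices and
    eligible scan-period indices; windowing takes prefixes of both.
    """

    records: list[ScanRecord]
    roster: dict[NodeId, dict] = field(default_factory=dict)
    days: tuple[int, ...] = ()
    periods: tuple[int, ...] = ()
    n_dropped_self: int = 0
    n_dropped_unknown: int = 0

    @classmethod
    def from_records(
        cls,
        records: Iterable[ScanRecord],
        roster: Mapping[NodeId, dict] | Iterable[NodeId] | None = None,
    ) -> "ScanLog":
        """Build a log: dedup records, drop off-roster rows, derive schedule.

        When ``roster`` is None it is inferred from the ids appearing in
        the records (scanners and detected alike, no attributes).
        """
        records = list(records)
        if roster is None:
            ids = {r.scanner for r in records} | {r.detected for r in records}
            roster_d: dict[NodeId, dict] = {i: {} for i in sorted(ids, key=repr)}
            n_unknown = 0
            kept = records
        else:
            roster_d = (
                {k: dict(v) for k, v in roster.items()}
                if isinstance(roster, Mapping)
                else {i: {} for i in roster}
            )
            kept = [
                r
                for r in records
                if r.scanner in roster_d and r.detected in roster_d
            ]
            n_unknown = len(records) - len(kept)
        deduped = sorted(set(kept))
        days = tuple(sorted({r.day for r in deduped}))
        periods = tuple(sorted({r.period for r in deduped}))
        return cls(
            records=deduped,
            roster=roster_d,
            days=days,
            periods=periods,
            n_dropped_unknown=n_unknown,
        )

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Records as a DataFrame (scanner, detected, wave, day, period)."""
        return pd.DataFrame(
            [(r.scanner, r.detected, r.wave, r.day, r.period) for r in self.records],
            columns=["scanner", "detected", "wave", "day", "period"],
        )

    def replace_records(self, records: Iterable[ScanRecord]) -> "ScanLog":
        """New log with the same roster but a different record set."""
        new = ScanLog.from_records(records, roster=self.roster)
        new.n_dropped_self = self.n_dropped_self
        return new


@dataclass(frozen=True, order=True)
class NominationRecord:
    """A directed peer nomination on one of the six sociometric items."""

    nominator: NodeId
    nominee: NodeId
    item: int  # 1..6: advice, friends, leader, respect, hang out, want-to-be
    wave: str = "W1"

    def __post_init__(self) -> None:
        if self.nominator == self.nominee:
            raise ValueError(f"self-nomination by {self.nominator!r}")
        if not 1 <= self.item <= 6:
            raise ValueError(f"item must be in 1..6, got {self.item}")


def _parse_ordinal(value, prefix: str, line: int | None = None) -> int:
    """Parse '3', 'S3' or 'D3' into the integer 3."""
    s = str(value).strip()
    if s[:1].upper() == prefix.upper():
        s = s[1:]
    try:
        return int(s)
    except ValueError:
        loc = f" (line {line})" if line is not None else ""
        raise FormatError(f"cannot parse {prefix!r}-label {value!r}{loc}") from None


def read_scan_log(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    roster: Mapping[NodeId, dict] | Iterable[NodeId] | None = None,
) -> ScanLog:
    """Read a scan-log CSV into a deduplicated :class:`ScanLog`.

    ``dialect`` maps the logical fields (scanner, detected, wave, day,
    period) to the file's column names; missing entries fall back to
    :data:`DEFAULT_DIALECT`.  Rows where a device detected itself are
    dropped and tallied on the returned log.
    """
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    df = pd.read_csv(path, dtype=str)
    for logical in ("scanner", "detected", "wave", "day", "period"):
        if dia[logical] not in df.columns:
            raise FormatError(
                f"scan log {path} is missing mapped column {dia[logical]!r} "
                f"(logical field {logical!r})"
            )
    records: list[ScanRecord] = []
    n_self = 0
    for line, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        scanner = row_d[dia["scanner"]]
        detected = row_d[dia["detected"]]
        if scanner == detected:
            n_self += 1
            continue
        records.append(
            ScanRecord(
                scanner=scanner,
                detected=detected,
                wave=str(row_d[dia["wave"]]),
                day=_parse_ordinal(row_d[dia["day"]], "D", line),
                period=_parse_ordinal(row_d[dia["period"]], "S", line),
            )
        )
    log = ScanLog.from_records(records, roster=roster)
    log.n_dropped_self = n_self
    return log


def write_scan_log(
    log: ScanLog, path: str | Path, dialect: Mapping[str, str] | None = None
) -> None:
    """Write a scan log back to CSV in the given dialect (default schema)."""
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([dia[k] for k in ("scanner", "detected", "wave", "day", "period")])
        for r in log.records:
            w.writerow([r.scanner, r.detected, r.wave, f"D{r.day}", f"S{r.period}"])


def read_roster(path: str | Path) -> dict[NodeId, dict]:
    """Read a roster CSV with columns node_id[,gender][,class]."""
    df = pd.read_csv(path, dtype=str)
    if "node_id" not in df.columns:
        raise FormatError(f"roster {path} is missing column 'node_id'")
    attrs = [c for c in df.columns if c != "node_id"]
    return {
        row["node_id"]: {a: row[a] for a in attrs}
        for _, row in df.iterrows()
    }


def read_nominations(path: str | Path) -> list[NominationRecord]:
    """Read a nomination CSV (nominator, nominee, item, wave).

    Rows with ``item`` outside 1..6 are rejected with a row-level error;
    self-nominations are dropped (tallying them is left to callers that
    care — they carry no information for network construction).
    """
    df = pd.read_csv(path, dtype=str)
    for col in ("nominator", "nominee", "item", "wave"):
        if col not in df.columns:
            raise FormatError(f"nomination table {path} is missing column {col!r}")
    records = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        try:
            item = int(row_d["item"])
        except ValueError:
            raise FormatError(f"non-integer item {row_d['item']!r} (line {line})") from None
        if not 1 <= item <= 6:
            raise FormatError(f"item {item} out of range 1..6 (line {line})")
        if row_d["nominator"] == row_d["nominee"]:
            continue
        records.append(
            NominationRecord(
                nominator=row_d["nominator"],
                nominee=row_d["nominee"],
                item=item,
                wave=str(row_d["wave"]),
            )
        )
    return records


def write_nominations(records: Sequence[NominationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["nominator", "nominee", "item", "wave"])
        for r in sorted(records):
            w.writerow([r.nominator, r.nominee, r.item, r.wave])


def read_friendship_matrix(path: str | Path) -> nx.Graph | nx.DiGraph:
    """Read a binary adjacency CSV (first column = node ids, header = ids).

    A symmetric matrix yields an undirected graph; an asymmetric one a
    directed graph (flagged via ``G.graph['directed']``).  The diagonal
    is ignored.  All edges carry weight 1.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"adjacency matrix {path} is not square: {df.shape}")
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError(f"adjacency matrix {path}: row/column labels differ")
    vals = df.to_numpy()
    if not ((vals == 0) | (vals == 1)).all():
        raise FormatError(f"adjacency matrix {path} contains non-binary cells")
    symmetric = (vals == vals.T).all()
    G: nx.Graph | nx.DiGraph = nx.Graph() if symmetric else nx.DiGraph()
    G.add_nodes_from(df.index)
    n = len(df.index)
    for a in range(n):
        for b in range(n):
            if a != b and vals[a, b] == 1:
                G.add_edge(df.index[a], df.index[b], weight=1.0)
    G.graph["directed"] = not symmetric
    G.graph["provenance"] = "matrix"
    return G


def filter_participation(
    roster: Iterable[NodeId] | int, class_size: int, threshold: float = 0.6
) -> tuple[bool, float]:
    """Class-level participation check: strictly more than ``threshold``.

    Returns ``(passes, rate)`` where ``rate = participants / class_size``.
    The comparison is strict: a class participating at exactly the
    threshold fraction fails.
    """
    n = roster if isinstance(roster, int) else len(list(roster))
    if class_size <= 0:
        raise ValueError("class_size must be positive")
    if not 0 < n <= class_size:
        raise ValueError(f"participant count {n} not in 1..{class_size}")
    rate = n / class_size
    return rate > threshold, rate


def filter_scan_periods(
    log: ScanLog, min_obs: int = 30, per_day: bool = False
) -> ScanLog:
    """Drop scan periods that collected fewer than ``min_obs`` records.

    By default observation counts are aggregated per (wave, period) over
    days; with ``per_day=True`` each (wave, day, period) cell must reach
    the minimum on its own.  With ``min_obs=0`` this is the identity.
    """
    if min_obs < 0:
        raise ValueError("min_obs must be >= 0")
    if min_obs == 0 or not log.records:
        return log.replace_records(log.records)
    if per_day:
        counts: dict = {}
        for r in log.records:
            counts[(r.wave, r.day, r.period)] = counts.get((r.wave, r.day, r.period), 0) + 1
        kept = [r for r in log.records if counts[(r.wave, r.day, r.period)] >= min_obs]
    else:
        counts = {}
        for r in log.records:
            counts[(r.wave, r.period)] = counts.get((r.wave, r.period), 0) + 1
        kept = [r for r in log.records if counts[(r.wave, r.period)] >= min_obs]
    return log.replace_records(kept)


def write_network(
    net: nx.Graph | nx.DiGraph, path: str | Path, fmt: str = "edgelist"
) -> None:
    """Write a network as an edge-list CSV or GraphML.

    The edge list holds ``source,target,weight`` rows only (isolates are
    not representable there); GraphML round-trips the full node set and
    attributes.
    """
    path = Path(path)
    if fmt == "edgelist":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "weight"])
            for u, v, d in sorted(net.edges(data=True), key=lambda e: (repr(e[0]), repr(e[1]))):
                w.writerow([u, v, d.get("weight", 1.0)])
    elif fmt == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path: str | Path, fmt: str = "edgelist", directed: bool = False):
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if fmt == "edgelist":
        G: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                G.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        return G
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {fmt!r}")
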