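"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import pytest

from socioscan.bva import ConfusionCounts
from socioscan.io import ScanLog, ScanRecord


def make_log(rows, roster=None):
    """ScanLog from (scanner, detected, day, period) tuples, wave W1."""
    records = [
        ScanRecord(scanner=a, detected=b, wave="W1", day=d, period=p)
        for a, b, d, p in rows
    ]
    return ScanLog.from_records(records, roster=roster)


def oracle_confusion(bt, gt, roster):
    """Brute-force pairwise enumerator, independent of the pipeline path.

    Walks every (un)ordered roster pair and classifies it by direct
    has_edge membership tests on the two graphs.
    """
    roster = sorted(roster, key=repr)
    directed = bt.is_directed()
    if directed:
        pairs = [(i, j) for i in roster for j in roster if i != j]
    else:
        pairs = list(itertools.combinations(roster, 2))
    tp = tn = fp = fn = 0
    for i, j in pairs:
        in_bt = bt.has_edge(i, j)
        in_gt = gt.has_edge(i, j)
        if in_bt and in_gt:
            tp += 1
        elif in_bt:
            fp += 1
        elif in_gt:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def oracle_mcc(c: ConfusionCounts) -> float:
    """Straight transcription of the MCC formula, zero-denominator -> 0."""
    d = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if d == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(d)


@pytest.fixture
def tiny_log():
    """Three nodes, two days, three periods, with one repeated detection."""
    return make_log(
        [
            ("a", "b", 1, 0),
            ("a", "b", 1, 1),
            ("b", "a", 1, 0),
            ("a", "c", 2, 0),
            ("c", "a", 2, 2),
        ]
    )
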