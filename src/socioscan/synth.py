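"""Synthetic classroom generator: planted friendship networks and noisy
proximity scan logs.

The generator emulates a school-class proximity study: a roster of
pupils with genders, a nomination-based ground-truth network with
gender homophily and a few hub (popular) pupils, and a multi-day
Bluetooth scan log in which participation is uneven, tied pairs are
detected with some probability per slot, untied pairs occasionally
produce false-positive detections, and genuine detections are sometimes
missed.  Every draw is governed by the config seed, with per-(day,
slot) substreams, so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Hashable

import networkx as nx
import numpy as np

from .ground_truth import build_gt_directed, build_gt_undirected
from .io import NominationRecord, ScanLog, ScanRecord

__all__ = ["SimConfig", "build_schedule", "generate_gt", "simulate_scan_log", "generate_study"]

NodeId = Hashable


def build_schedule(
    start: str = "07:00",
    end: str = "19:00",
    interval_minutes: int = 15,
    n_days: int = 5,
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Daily scan-slot schedule from a half-open [start, end) time span.

    Returns ``(days, slots)`` with 1-based day indices and 0-based slot
    indices; the slot count is floor((end - start) / interval).  A full
    day at a 5-minute cadence yields 288 slots.
    """
    sh, sm = (int(x) for x in start.split(":"))
    eh, em = (int(x) for x in end.split(":"))
    span = (eh * 60 + em) - (sh * 60 + sm)
    if span <= 0:
        span += 24 * 60  # spans crossing midnight, incl. full-day 00:00-00:00
    if interval_minutes <= 0:
        raise ValueError("interval must be positive")
    if interval_minutes > span:
        raise ValueError("interval exceeds the scheduled span")
    n_slots = span // interval_minutes
    if n_days < 1:
        raise ValueError("need at least one day")
    return tuple(range(1, n_days + 1)), tuple(range(n_slots))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated class.

    Defaults mirror a single well-participating primary-school class
    observed over one wave: 15 pupils, roughly balanced genders, strong
    gender homophily and a few popular hubs in the friendship network,
    five days of quarter-hour daytime scan slots, and sparse, uneven
    scanner participation.
    """

    n_nodes: int = 15
    female_fraction: float = 0.53
    homophily: float = 0.7  # probability a nomination targets a same-gender peer
    hub_count: int = 3
    hub_boost: float = 3.0  # selection-weight multiplier for hub nominees
    mean_out_degree: float = 7.0  # expected nominees per pupil
    items_lambda: float = 1.5  # ties carry min(6, 1 + Poisson(lambda)) items
    schedule: tuple[tuple[int, ...], tuple[int, ...]] = field(
        default_factory=lambda: build_schedule("07:00", "19:00", 15, 5)
    )
    p_participate: float = 0.18  # per-node per-slot scanner probability
    p_detect_edge: float = 0.6  # per-slot detection probability for tied pairs
    p_false_positive: float = 0.02  # per-slot detection probability, untied pairs
    p_miss: float = 0.1  # false-negative rate on genuine detections
    wave: str = "W1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        for name in (
            "female_fraction",
            "homophily",
            "p_participate",
            "p_detect_edge",
            "p_false_positive",
            "p_miss",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def node_ids(self) -> list[str]:
        # Three-digit ids starting at 901, matching the field convention
        # of labelling pupils with short numeric codes.
        return [f"{901 + k}" for k in range(self.n_nodes)]


def _gender_map(cfg: SimConfig) -> dict[str, str]:
    ids = cfg.node_ids()
    n_female = round(cfg.female_fraction * cfg.n_nodes)
    return {nid: ("F" if k < n_female else "M") for k, nid in enumerate(ids)}


def generate_gt(cfg: SimConfig) -> tuple[list[NominationRecord], dict[str, str]]:
    """Draw a nomination table with planted homophily and hub structure.

    Each pupil nominates a Binomial-thinned set of peers; candidate
    nominees of the same gender are preferred with probability
    ``homophily`` and hubs carry ``hub_boost``-fold selection weight.
    Every realized directed tie receives min(6, 1 + Poisson(lambda))
    distinct items.
    """
    rng = np.random.default_rng([cfg.seed, 11])
    ids = cfg.node_ids()
    gender = _gender_map(cfg)
    hubs = set(ids[: cfg.hub_count])
    noms: list[NominationRecord] = []
    p_tie = min(1.0, cfg.mean_out_degree / max(1, cfg.n_nodes - 1))
    for i in ids:
        n_out = rng.binomial(cfg.n_nodes - 1, p_tie)
        if n_out == 0:
            continue
        same = [j for j in ids if j != i and gender[j] == gender[i]]
        other = [j for j in ids if j != i and gender[j] != gender[i]]
        chosen: set[str] = set()
        for _ in range(n_out):
            pool = same if (same and (not other or rng.random() < cfg.homophily)) else other
            candidates = [j for j in pool if j not in chosen]
            if not candidates:
                # chosen pool exhausted: forfeit the attempt rather than
                # cross genders, so homophily=1 stays exactly homophilous
                continue
            w = np.array([cfg.hub_boost if j in hubs else 1.0 for j in candidates])
            j = candidates[rng.choice(len(candidates), p=w / w.sum())]
            chosen.add(j)
        for j in sorted(chosen):
            n_items = min(6, 1 + rng.poisson(cfg.items_lambda))
            items = rng.choice(6, size=n_items, replace=False) + 1
            for item in sorted(int(x) for x in items):
                noms.append(NominationRecord(nominator=i, nominee=j, item=item, wave=cfg.wave))
    return noms, gender


def simulate_scan_log(gt: nx.Graph | nx.DiGraph, cfg: SimConfig) -> ScanLog:
    """Simulate the noisy Bluetooth scan log implied by a GT network.

    A tie between i and j (an edge in either direction) makes mutual
    detection likely; per slot, each pupil participates as a scanner
    with ``p_participate``, detects co-participating tied peers with
    ``p_detect_edge * (1 - p_miss)``, and co-participating untied peers
    with ``p_false_positive``.
    """
    ids = cfg.node_ids()
    id_index = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    tied = np.zeros((n, n), dtype=bool)
    for u, v in gt.edges():
        if u in id_index and v in id_index:
            tied[id_index[u], id_index[v]] = True
            tied[id_index[v], id_index[u]] = True
    p_hit = cfg.p_detect_edge * (1.0 - cfg.p_miss)
    days, slots = cfg.schedule
    records: list[ScanRecord] = []
    for day in days:
        for slot in slots:
            rng = np.random.default_rng([cfg.seed, 7, day, slot])
            present = rng.random(n) < cfg.p_participate
            if present.sum() < 2:
                continue
            u = rng.random((n, n))
            prob = np.where(tied, p_hit, cfg.p_false_positive)
            hit = (u < prob) & present[:, None] & present[None, :]
            np.fill_diagonal(hit, False)
            for a, b in zip(*hit.nonzero()):
                records.append(
                    ScanRecord(
                        scanner=ids[a],
                        detected=ids[b],
                        wave=cfg.wave,
                        day=int(day),
                        period=int(slot),
                    )
                )
    roster = {nid: {"gender": g} for nid, g in _gender_map(cfg).items()}
    return ScanLog.from_records(records, roster=roster)


def generate_study(cfg: SimConfig) -> dict:
    """One full synthetic study: nominations, GT networks, gender, scan log."""
    noms, gender = generate_gt(cfg)
    roster = {nid: {"gender": gender[nid]} for nid in cfg.node_ids()}
    gt_dir = build_gt_directed(noms, roster)
    gt_und = build_gt_undirected(noms, roster)
    log = simulate_scan_log(gt_und, cfg)
    return {
        "config": cfg,
        "nominations": noms,
        "gender": gender,
        "roster": roster,
        "gt": {"directed": gt_dir, "undirected": gt_und},
        "log": log,
    }
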