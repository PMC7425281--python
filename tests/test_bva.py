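"""Brute-force validation: grid, confusion metrics, selection, baseline."""

import random

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socioscan.bva import (
    ConfusionCounts,
    GridSpec,
    accuracy,
    baseline,
    confusion,
    count_distinct,
    default_weight_values,
    enumerate_grid,
    mcc,
    run_grid,
    select_optimal,
)
from socioscan.ground_truth import build_gt_undirected
from socioscan.inference import SmoothingParams, WindowSpec, build_bt_network
from socioscan.io import NominationRecord

from conftest import make_log, oracle_confusion, oracle_mcc


class TestGrid:
    def test_default_weight_grid_has_sixty_values(self):
        vals = default_weight_values()
        assert len(vals) == 60
        assert vals[0] == pytest.approx(0.01) and vals[-1] == pytest.approx(0.60)
        assert 0.0 not in vals

    def test_standard_grid_cardinality(self):
        spec = GridSpec.default(n_days=5, n_scans=16)
        assert len(enumerate_grid(spec)) == 4800

    def test_tiny_grid(self):
        spec = GridSpec((0.1,), (1,), (1,))
        assert len(enumerate_grid(spec)) == 1

    def test_product_matches_hand_enumeration(self):
        spec = GridSpec((0.1, 0.2), (1, 2, 3), (1, 2, 3, 4))
        tuples = enumerate_grid(spec)
        assert len(tuples) == 24
        assert len(set(tuples)) == 24
        assert tuples == sorted(tuples, key=lambda t: (t[0], t[1], t[2], t[3]))

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            GridSpec((), (1,), (1,))

    def test_nonincreasing_weights_rejected(self):
        with pytest.raises(ValueError):
            GridSpec((0.2, 0.1), (1,), (1,))


def _net(edges, nodes, directed=False):
    G = nx.DiGraph() if directed else nx.Graph()
    G.add_nodes_from(nodes)
    G.add_edges_from(edges)
    return G


class TestConfusion:
    NODES = list("ABCD")

    def test_identical_networks(self):
        gt = _net([("A", "B"), ("B", "C")], self.NODES)
        c = confusion(gt, gt, self.NODES)
        assert (c.fp, c.fn) == (0, 0) and c.tp == 2 and c.tn == 4

    def test_hand_enumerated_example(self):
        gt = _net([("A", "B"), ("B", "C")], self.NODES)
        bt = _net([("A", "B"), ("C", "D")], self.NODES)
        c = confusion(bt, gt, self.NODES)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 3)

    def test_complement_prediction(self):
        gt = _net([("A", "B"), ("B", "C")], self.NODES)
        bt = nx.complement(gt)
        c = confusion(bt, gt, self.NODES)
        assert c.tp == 0 and c.tn == 0

    def test_mixed_directedness_errors(self):
        with pytest.raises(ValueError):
            confusion(_net([], self.NODES, True), _net([], self.NODES), self.NODES)

    def test_totals_conserve_pair_universe(self):
        rng = random.Random(2)
        nodes = [f"n{k}" for k in range(7)]
        for directed in (False, True):
            for _ in range(10):
                all_pairs = [
                    (a, b) for a in nodes for b in nodes
                    if a != b and (directed or a < b)
                ]
                gt = _net(rng.sample(all_pairs, 8), nodes, directed)
                bt = _net(rng.sample(all_pairs, 8), nodes, directed)
                c = confusion(bt, gt, nodes)
                expect = len(nodes) * (len(nodes) - 1)
                assert c.total == (expect if directed else expect // 2)

    def test_matches_independent_enumerator(self):
        rng = random.Random(21)
        nodes = [f"n{k}" for k in range(6)]
        pairs = [(a, b) for a in nodes for b in nodes if a < b]
        for _ in range(25):
            gt = _net(rng.sample(pairs, rng.randint(0, len(pairs))), nodes)
            bt = _net(rng.sample(pairs, rng.randint(0, len(pairs))), nodes)
            assert confusion(bt, gt, nodes) == oracle_confusion(bt, gt, nodes)


class TestMetrics:
    def test_accuracy_hand_value(self):
        assert accuracy(ConfusionCounts(1, 3, 1, 1)) == pytest.approx(4 / 6)

    def test_accuracy_perfect_and_complement(self):
        assert accuracy(ConfusionCounts(3, 3, 0, 0)) == 1.0
        assert accuracy(ConfusionCounts(0, 0, 3, 3)) == 0.0

    def test_accuracy_empty_universe_errors(self):
        with pytest.raises(ValueError):
            accuracy(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_perfect_classification(self):
        assert mcc(ConfusionCounts(tp=5, tn=10, fp=0, fn=0)) == pytest.approx(1.0)

    def test_mcc_perfect_misclassification(self):
        assert mcc(ConfusionCounts(tp=0, tn=0, fp=10, fn=5)) == pytest.approx(-1.0)

    def test_mcc_hand_value(self):
        assert mcc(ConfusionCounts(1, 3, 1, 1)) == pytest.approx(0.25)

    def test_mcc_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(0, 5, 0, 0)) == 0.0

    @given(
        tp=st.integers(0, 30), tn=st.integers(0, 30),
        fp=st.integers(0, 30), fn=st.integers(0, 30),
    )
    @settings(max_examples=200, derandomize=True)
    def test_mcc_bounded_and_matches_oracle(self, tp, tn, fp, fn):
        c = ConfusionCounts(tp, tn, fp, fn)
        v = mcc(c)
        assert -1.0 <= v <= 1.0
        assert v == pytest.approx(oracle_mcc(c))

    def test_mcc_sign_flips_under_complement(self):
        c = ConfusionCounts(tp=4, tn=4, fp=1, fn=1)
        flipped = ConfusionCounts(tp=c.fn, tn=c.fp, fp=c.tn, fn=c.tp)
        assert mcc(flipped) == pytest.approx(-mcc(c))


def small_study(seed=0, n_nodes=5):
    """Tiny (log, gt) pair with a planted undirected GT."""
    rng = random.Random(seed)
    nodes = [f"n{k}" for k in range(n_nodes)]
    noms = []
    for a in nodes:
        for b in nodes:
            if a != b and rng.random() < 0.4:
                for item in rng.sample(range(1, 7), rng.randint(1, 3)):
                    noms.append(NominationRecord(a, b, item))
    gt = build_gt_undirected(noms, nodes)
    rows = []
    for day in (1, 2):
        for period in range(4):
            for a in nodes:
                for b in nodes:
                    if a == b:
                        continue
                    p = 0.6 if gt.has_edge(a, b) else 0.1
                    if rng.random() < p:
                        rows.append((a, b, day, period))
    return make_log(rows, roster=nodes), gt


class TestRunGrid:
    def test_single_tuple_at_threshold_zero_equals_baseline(self):
        log, gt = small_study(1)
        spec = GridSpec((0.0,), (len(log.days),), (len(log.periods),))
        res = run_grid(log, gt, spec)
        base = baseline(log, gt, "undirected")
        assert len(res) == 1
        assert res[0].metric_value == base.metric_value
        assert res[0].confusion == base.confusion
        assert res[0].fingerprint == base.fingerprint

    def test_results_match_fresh_network_construction(self):
        """Each grid point equals building the network from scratch and
        scoring it with the independent pairwise enumerator."""
        log, gt = small_study(2)
        spec = GridSpec(
            (0.05, 0.2, 0.4), (1, 2), (2, 4), ("undirected",), "accuracy"
        )
        for r in run_grid(log, gt, spec):
            net = build_bt_network(
                log, WindowSpec(r.n_days, r.n_scans), r.ctype, r.weight
            )
            c = oracle_confusion(net, gt, log.roster)
            assert r.confusion == c
            assert r.metric_value == pytest.approx(accuracy(c))

    def test_observation_count_is_window_record_count(self):
        log, gt = small_study(3)
        spec = GridSpec((0.1,), (1,), (2,))
        from socioscan.inference import window_log

        r = run_grid(log, gt, spec)[0]
        assert r.n_bt_observations == len(window_log(log, WindowSpec(1, 2)))

    def test_deterministic_across_runs(self):
        log, gt = small_study(4)
        spec = GridSpec((0.1, 0.3), (1, 2), (1, 2))
        a = run_grid(log, gt, spec)
        b = run_grid(log, gt, spec)
        assert a == b


class TestDistinctAndSelection:
    def test_identical_networks_collapse_to_one(self):
        log, gt = small_study(5)
        spec = GridSpec((0.001, 0.002), (len(log.days),), (len(log.periods),))
        res = run_grid(log, gt, spec)
        # thresholds far below any realized weight: same network twice
        n_vals, n_nets = count_distinct(res)
        assert n_nets == 1 and n_vals == 1

    def test_thresholds_straddling_a_weight_give_two_networks(self):
        log = make_log([("i", "j", 1, 0), ("j", "i", 1, 1), ("i", "k", 1, 0)],
                       roster=["i", "j", "k"])
        noms = [NominationRecord("i", "j", 1)]
        gt = build_gt_undirected(noms, ["i", "j", "k"])
        # weights: (i,j) = 2/(1+1+1) ~ 0.667, (i,k) = 1/(1+0+1) = 0.5
        spec = GridSpec((0.45, 0.55), (1,), (2,))
        res = run_grid(log, gt, spec)
        assert count_distinct(res)[1] == 2

    def test_single_result_selects_itself(self):
        log, gt = small_study(6)
        res = run_grid(log, gt, GridSpec((0.1,), (1,), (1,)))
        best, trace = select_optimal(res)
        assert best == res[0] and trace["n_at_best_metric"] == 1

    def test_tie_broken_by_fewer_observations(self):
        log, gt = small_study(7)
        spec = GridSpec((0.001, 0.002), (len(log.days),), (1, len(log.periods)))
        res = run_grid(log, gt, spec)
        same = [r for r in res if r.metric_value == max(x.metric_value for x in res)]
        best, _ = select_optimal(res)
        assert best.n_bt_observations == min(r.n_bt_observations for r in same)

    def test_shuffling_results_does_not_change_selection(self):
        log, gt = small_study(8)
        spec = GridSpec((0.05, 0.2, 0.4), (1, 2), (1, 2, 4))
        res = run_grid(log, gt, spec)
        rng = random.Random(0)
        for _ in range(5):
            shuffled = res[:]
            rng.shuffle(shuffled)
            assert select_optimal(shuffled)[0] == select_optimal(res)[0]

    def test_optimal_dominates_every_grid_member(self):
        log, gt = small_study(9)
        spec = GridSpec((0.05, 0.2, 0.4), (1, 2), (1, 2, 4))
        res = run_grid(log, gt, spec)
        best, _ = select_optimal(res)
        assert all(best.metric_value >= r.metric_value for r in res)


class TestBaseline:
    def test_baseline_uses_threshold_zero_and_full_window(self):
        log, gt = small_study(10)
        b = baseline(log, gt, "undirected")
        assert b.weight == 0.0
        assert b.n_days == len(log.days) and b.n_scans == len(log.periods)

    def test_baseline_equals_matching_grid_tuple(self):
        log, gt = small_study(11)
        spec = GridSpec((0.0, 0.1), (1, len(log.days)), (1, len(log.periods)))
        res = run_grid(log, gt, spec)
        b = baseline(log, gt, "undirected")
        match = [
            r for r in res
            if r.weight == 0.0 and r.n_days == b.n_days and r.n_scans == b.n_scans
        ]
        assert match and match[0].confusion == b.confusion
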