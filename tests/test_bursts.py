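"""logISI thresholds, burst runs vs brute-force oracle, network bursts and
feedforward propagation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import meacircuit as mc
from meacircuit.bursts import BurstParams, _node_onset

from conftest import make_table


def brute_force_bursts(times, threshold, min_spikes):
    """Independent oracle: enumerate maximal runs of ISIs <= threshold."""
    times = list(times)
    runs, cur = [], [0]
    for i in range(1, len(times)):
        if times[i] - times[i - 1] <= threshold:
            cur.append(i)
        else:
            runs.append(cur)
            cur = [i]
    if cur:
        runs.append(cur)
    return [
        (times[r[0]], times[r[-1]], len(r)) for r in runs if len(r) >= min_spikes
    ]


class TestIsiThreshold:
    def test_bimodal_threshold_between_modes(self):
        rng = np.random.default_rng(0)
        isis = np.concatenate([
            rng.normal(0.005, 0.001, 500).clip(1e-4),
            rng.normal(1.0, 0.2, 500).clip(0.3),
        ])
        rng.shuffle(isis)
        t = np.cumsum(isis)
        thr = mc.isi_threshold_logisi(t)
        assert 0.005 < thr <= 0.100

    def test_all_isis_above_cap_returns_cap(self):
        t = np.arange(50) * 0.150
        assert mc.isi_threshold_logisi(t) == 0.100

    def test_unimodal_returns_cap_fallback(self):
        t = np.arange(50) * 0.010
        assert mc.isi_threshold_logisi(t) == 0.100

    def test_too_few_spikes(self):
        assert mc.isi_threshold_logisi(np.array([1.0])) is None


class TestDetectBursts:
    def test_two_separated_bursts(self):
        t = np.concatenate([0.01 * np.arange(4), 2.0 + 0.01 * np.arange(4)])
        bursts = mc.detect_bursts(t, 0.1, "e")
        assert [(b.n_spikes) for b in bursts] == [4, 4]
        assert bursts[0].start == 0.0 and bursts[1].start == 2.0

    def test_three_spikes_insufficient(self):
        assert mc.detect_bursts(np.array([0.0, 0.01, 0.02]), 0.1, "e") == []

    def test_isi_at_threshold_boundary_included(self):
        t = np.arange(10) * 0.099
        bursts = mc.detect_bursts(t, 0.100, "e")
        assert len(bursts) == 1 and bursts[0].n_spikes == 10

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 30.0), min_size=0, max_size=20),
        st.floats(0.005, 0.2),
    )
    def test_matches_brute_force_oracle(self, raw_times, threshold):
        t = np.unique(np.round(np.asarray(raw_times), 4))
        expected = brute_force_bursts(t, threshold, 4)
        got = mc.detect_bursts(t, threshold, "e")
        assert [(b.start, b.end, b.n_spikes) for b in got] == expected

    def test_bursts_never_overlap(self, sim_table):
        table, _ = sim_table
        bursts, _ = mc.detect_bursts_table(table)
        by = {}
        for b in bursts:
            by.setdefault(b.electrode_id, []).append(b)
        for bs in by.values():
            bs.sort(key=lambda b: b.start)
            for a, b in zip(bs, bs[1:]):
                assert a.end < b.start

    def test_constituent_isis_below_cap(self, sim_table):
        table, _ = sim_table
        bursts, thresholds = mc.detect_bursts_table(table)
        by = table.by_electrode()
        for b in bursts[:100]:
            t = by[b.electrode_id]
            run = t[(t >= b.start) & (t <= b.end)]
            assert np.diff(run).max() <= thresholds[b.electrode_id] + 1e-12
            assert thresholds[b.electrode_id] <= 0.100


class TestActiveElectrodes:
    def test_rate_boundary_inclusive(self, small_map):
        t = make_table(
            {"C01": np.linspace(0.1, 899, 90), "C02": [10.0]}, 900.0, small_map
        )
        act = mc.active_electrodes(t)
        assert "C01" in act and "C02" not in act

    def test_empty_table_no_active(self, small_map):
        assert mc.active_electrodes(make_table({}, 10.0, small_map)) == set()


class TestNetworkBursts:
    def _bursts_at(self, t0, eids, dur=0.1, n=4):
        return [mc.Burst(e, t0 + 0.001 * i, t0 + 0.001 * i + dur, n)
                for i, e in enumerate(eids)]

    def test_ten_percent_rule_boundary(self):
        active = {f"a{i}" for i in range(50)}
        bursts = self._bursts_at(10.0, [f"a{i}" for i in range(5)])
        nbs = mc.detect_network_bursts(bursts, active)
        assert len(nbs) == 1  # 5 of 50 = exactly 10%, inclusive

    def test_below_ten_percent_rejected(self):
        active = {f"a{i}" for i in range(50)}
        bursts = self._bursts_at(10.0, [f"a{i}" for i in range(4)])
        assert mc.detect_network_bursts(bursts, active) == []

    def test_two_events_split_with_correct_extent(self):
        active = {f"a{i}" for i in range(20)}
        eids = [f"a{i}" for i in range(20)]
        bursts = self._bursts_at(10.0, eids) + self._bursts_at(15.0, eids)
        nbs = mc.detect_network_bursts(bursts, active)
        assert len(nbs) == 2
        assert nbs[0].start == pytest.approx(10.0)
        assert nbs[0].end == pytest.approx(10.0 + 0.019 + 0.1)
        assert nbs[1].start == pytest.approx(15.0)

    def test_network_bursts_never_overlap(self, sim_table):
        table, _ = sim_table
        bursts, _ = mc.detect_bursts_table(table)
        act = mc.active_electrodes(table)
        nbs = mc.detect_network_bursts(bursts, act, electrode_map=table.electrode_map)
        for a, b in zip(nbs, nbs[1:]):
            assert a.start <= b.start


class TestClassifyPropagation:
    def _nb(self, onsets):
        return mc.NetworkBurst(0.0, 1.0, frozenset({"x"}), dict(onsets))

    def test_full_feedforward(self):
        nb = mc.classify_propagation(
            self._nb({"C": 1.0, "H1": 1.02, "H2": 1.04, "H3": 1.06})
        )
        assert (nb.initiation_node, nb.span, nb.feedforward) == ("C", 4, True)

    def test_partial_chain_from_h1(self):
        nb = mc.classify_propagation(self._nb({"H1": 2.0, "H2": 2.03}))
        assert (nb.initiation_node, nb.span, nb.feedforward) == ("H1", 2, False)

    def test_order_violation_breaks_chain(self):
        nb = mc.classify_propagation(self._nb({"C": 1.0, "H1": 0.98}))
        assert nb.initiation_node == "H1"
        assert nb.feedforward is False

    def test_skipped_node_breaks_chain(self):
        nb = mc.classify_propagation(self._nb({"C": 1.0, "H2": 1.04, "H3": 1.06}))
        assert (nb.initiation_node, nb.span) == ("C", 1)

    def test_tie_resolves_upstream_and_flags(self):
        nb = mc.classify_propagation(self._nb({"C": 1.0, "H1": 1.0}))
        assert nb.initiation_node == "C"
        assert nb.onset_tie_flag

    def test_leading_outlier_rejected_in_node_onset(self):
        # isolated early start (tonic spike glued to a burst) is discarded
        assert _node_onset([0.90, 1.000, 1.002, 1.003], 0.010) == 1.000
        assert _node_onset([0.998, 1.000, 1.002], 0.010) == 0.998
        assert _node_onset([0.90], 0.010) == 0.90


class TestPropagationSummary:
    def test_all_span4(self):
        nbs = [
            mc.classify_propagation(
                mc.NetworkBurst(i, i + 0.1, frozenset({"x"}),
                                {"C": i, "H1": i + 0.02, "H2": i + 0.04, "H3": i + 0.06})
            )
            for i in range(10)
        ]
        s = mc.propagation_summary(nbs)
        assert s["n_network_bursts"] == 10
        assert s["percent_feedforward"] == 100.0

    def test_burst_rate_per_node(self, small_map):
        table = make_table({"C01": np.linspace(0, 899, 100)}, 900.0, small_map)
        bursts = [mc.Burst("C01", 10.0 * i, 10.0 * i + 1, 4) for i in range(30)]
        nb = mc.classify_propagation(
            mc.NetworkBurst(0, 1, frozenset({"C01"}), {"C": 0.0})
        )
        s = mc.propagation_summary([nb], bursts, table)
        # 30 bursts in 15 min on C01, 0 on C02 -> node median = 1 /min
        assert s["median_burst_rate_per_min_by_node"]["C"] == pytest.approx(1.0)


class TestSpanMonotonicity:
    def test_span4_fraction_monotone_in_ptx(self):
        fractions = []
        for p in (0.3, 0.6, 0.9):
            cfg = mc.NetworkSimConfig(nb_rate={"C": 20.0}, p_tx=p, seed=21,
                                      tonic_rate=0.5)
            table, gt = mc.simulate_spike_trains(cfg, 300.0)
            bursts, _ = mc.detect_bursts_table(table)
            act = mc.active_electrodes(table)
            nbs = mc.detect_network_bursts(bursts, act,
                                           electrode_map=table.electrode_map)
            c = [nb for nb in nbs if nb.initiation_node == "C"]
            fractions.append(sum(nb.span == 4 for nb in c) / len(c))
        assert fractions[0] < fractions[1] < fractions[2]
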