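"""Data model, HDF5/CSV round-trips and configuration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import meacircuit as mc
from meacircuit.io import load_recording, load_spike_table, save_recording, save_spike_table

from conftest import make_table


class TestElectrodeMap:
    def test_unknown_label_rejected(self):
        with pytest.raises(mc.FormatError, match="H4"):
            mc.ElectrodeMap([("e1", "C"), ("e2", "H4")])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(mc.FormatError, match="duplicate"):
            mc.ElectrodeMap([("e1", "C"), ("e1", "H1")])

    def test_default_layout_is_59_electrodes(self):
        emap = mc.default_electrode_map()
        assert len(emap) == 59
        assert len(emap.electrodes_in(mc.TUNNEL)) == 9
        assert sum(len(emap.electrodes_in(n)) for n in mc.NODE_ORDER) == 50


class TestRecordingRoundTrip:
    def test_round_trip_identity(self, tmp_path):
        emap = mc.ElectrodeMap([("e1", "C"), ("e2", "H1")])
        sig = np.random.default_rng(0).normal(0, 5, (2, 25000)).astype(np.float32)
        rec = mc.RawRecording(sig, 25000.0, emap, [0.25, 0.75],
                              {"div": 28, "condition": "control", "network_id": "n1"})
        path = tmp_path / "rec.h5"
        save_recording(rec, path)
        back = load_recording(path)
        np.testing.assert_array_equal(back.samples, sig)
        assert back.sampling_rate == 25000.0
        assert back.electrode_map == emap
        np.testing.assert_allclose(back.stimulation_times, [0.25, 0.75])
        assert back.metadata["div"] == 28
        assert back.metadata["condition"] == "control"

    def test_channel_shape_mismatch_is_format_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=np.zeros((3, 100), np.float32))
            f.create_dataset("sampling_rate", data=25000.0)
            g = f.create_group("electrode_map")
            g.create_dataset("id", data=np.array([b"e1", b"e2"]))
            g.create_dataset("node", data=np.array([b"C", b"H1"]))
        with pytest.raises(mc.FormatError, match="shape"):
            load_recording(path)

    def test_missing_sampling_rate_is_format_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=np.zeros((1, 100), np.float32))
        with pytest.raises(mc.FormatError, match="sampling_rate"):
            load_recording(path)

    def test_duration_from_samples(self):
        emap = mc.default_electrode_map()
        rec = mc.RawRecording(np.zeros((59, 1_500_000), np.float32), 25000.0, emap)
        assert rec.duration == 60.0


class TestSpikeTable:
    def test_empty_table(self, small_map):
        t = make_table({}, 10.0, small_map)
        assert len(t) == 0

    def test_round_trip(self, tmp_path, small_map):
        t = make_table({"C01": [0.1, 0.2, 0.3]}, 1.0, small_map)
        path = tmp_path / "spikes.csv"
        save_spike_table(t, path)
        back = load_spike_table(path, 1.0, small_map)
        np.testing.assert_allclose(back.times("C01"), [0.1, 0.2, 0.3])
        assert len(back) == 3

    def test_duplicate_row_rejected(self, small_map):
        df = pd.DataFrame(
            {"electrode_id": ["C01", "C01"], "spike_time_s": [0.5, 0.5]}
        )
        with pytest.raises(mc.FormatError, match="C01"):
            mc.SpikeTable(df, 1.0, small_map)

    def test_out_of_range_time_rejected(self, small_map):
        with pytest.raises(mc.FormatError):
            make_table({"C01": [2.0]}, 1.0, small_map)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(0.001, 9.999), min_size=0, max_size=20),
            min_size=1,
            max_size=4,
        )
    )
    def test_csv_round_trip_preserves_all_rows(self, tmp_path_factory, trains):
        emap = mc.simulation_electrode_map(1)
        spikes = {}
        for i, train in enumerate(trains):
            eid = emap.electrode_ids[i]
            t = np.unique(np.round(np.asarray(train), 6))
            spikes[eid] = t
        table = mc.SpikeTable.from_arrays(spikes, 10.0, emap)
        path = tmp_path_factory.mktemp("rt") / "s.csv"
        save_spike_table(table, path)
        back = load_spike_table(path, 10.0, emap)
        for eid in spikes:
            np.testing.assert_allclose(back.times(eid), spikes[eid], atol=1e-9)


class TestConfig:
    def test_defaults_match_recording_protocol(self):
        cfg = mc.AnalysisConfig()
        assert cfg.filter_order == 4
        assert (cfg.low_cut_hz, cfg.high_cut_hz) == (300.0, 3000.0)
        assert cfg.notch_freq_hz == 50.0
        assert cfg.threshold_multiplier == 9.0
        assert cfg.peak_lifetime_s == 0.001
        assert cfg.refractory_s == 0.0016
        assert cfg.min_spikes_per_burst == 4
        assert cfg.max_isi_s == 0.100
        assert cfg.network_burst_fraction == 0.10
        assert cfg.correlation_bin_s == 0.050
        assert cfg.max_lag_bins == 10
        assert cfg.edge_threshold == 0.1
        assert cfg.blank_after_s == 0.015
        assert cfg.psth_bin_s == 0.020
        assert cfg.psth_window_s == 0.300
        assert cfg.particle_min_diameter_um == 5.0
        assert cfg.um_per_px == pytest.approx(2803.0 / 2046.0)

    def test_yaml_round_trip_lossless(self, tmp_path):
        cfg = mc.AnalysisConfig(threshold_multiplier=7.5, seed=42)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = mc.AnalysisConfig.from_yaml(path)
        assert back.to_dict() == cfg.to_dict()
        assert back.content_hash() == cfg.content_hash()

    def test_invalid_values_rejected(self):
        with pytest.raises(mc.ConfigError):
            mc.AnalysisConfig(network_burst_fraction=0.0)
        with pytest.raises(mc.ConfigError):
            mc.AnalysisConfig(low_cut_hz=4000.0)
        with pytest.raises(mc.ConfigError):
            mc.AnalysisConfig.from_dict({"not_a_key": 1})
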