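"""Generator: determinism, schedule statistics, planted effects, fixture IO."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import mindstate as ms
from mindstate import experiments as ex
from mindstate import synthgen as sg
from mindstate.errors import ConfigurationError, FormatError, ParameterError


def tiny_config(**kw):
    base = dict(n_blocks=1, block_duration=60.0, seed=11)
    base.update(kw)
    return sg.SessionConfig(**base)


class TestStateTimecourse:
    def test_infinite_dwell_from_on_stays_on(self):
        cfg = tiny_config(state_dwell=float("inf"))
        st = sg.generate_state_timecourse(cfg, np.random.default_rng(0), init_state="ON")
        assert (st == sg.STATES.index("ON")).all()

    def test_same_seed_same_sequence(self):
        cfg = tiny_config()
        a = sg.generate_state_timecourse(cfg, np.random.default_rng(5))
        b = sg.generate_state_timecourse(cfg, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_empirical_dwell_matches_exponential_mean(self):
        # many complete segments; boundary-truncated ones are excluded
        cfg = tiny_config(n_blocks=4, block_duration=300.0, state_dwell=2.0)
        st = sg.generate_state_timecourse(cfg, np.random.default_rng(3))
        bounds = np.flatnonzero(np.diff(st)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [st.size]])
        block = cfg.block_samples
        keep = [(a, b) for a, b in zip(starts, stops)
                if a % block != 0 and b % block != 0]
        dwells = np.array([(b - a) / cfg.fs for a, b in keep])
        assert dwells.size > 100
        assert abs(dwells.mean() - 2.0) / 2.0 < 0.1

    def test_nonpositive_dwell_rejected(self):
        cfg = tiny_config(state_dwell=0.0)
        with pytest.raises(ParameterError):
            sg.generate_state_timecourse(cfg, np.random.default_rng(0))


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"soa_range": (0.0, 1000.0)},
        {"soa_range": (1300.0, 1200.0)},
        {"nogo_rate": 0.0},
        {"nogo_rate": 1.5},
        {"probe_interval_range": (70.0, 40.0)},
    ])
    def test_bad_parameters(self, kw):
        with pytest.raises(ParameterError):
            tiny_config(**kw).validate()

    def test_block_shorter_than_soa(self):
        with pytest.raises(ConfigurationError):
            tiny_config(block_duration=1.0).validate()


class TestSessionGeneration:
    def test_same_config_bit_identical(self):
        a = sg.generate_session(tiny_config())
        b = sg.generate_session(tiny_config())
        assert np.array_equal(a.data, b.data)
        assert a.events_frame().equals(b.events_frame())

    def test_events_sorted_and_in_range(self, small_recording):
        onsets = [e.onset for e in small_recording.events]
        assert onsets == sorted(onsets)
        assert max(onsets) < small_recording.n_samples

    def test_probe_intervals_within_block_jitter_range(self):
        cfg = tiny_config(n_blocks=2, block_duration=200.0)
        rec = sg.generate_session(cfg)
        ev = rec.events_frame()
        probes = ev[ev["kind"] == "probe_onset"]
        lo, hi = cfg.probe_interval_range
        for b, sub in probes.groupby("block"):
            gaps = np.diff(sub["onset"].to_numpy()) / cfg.fs
            assert ((gaps >= lo) & (gaps <= hi)).all()

    def test_nogo_fraction_binomial(self):
        # >= 5000 stimuli; cheap channels/sampling to keep it fast
        cfg = tiny_config(n_channels=4, fs=100.0, n_blocks=2, block_duration=2600.0,
                          coupling_pairs=((0, 2),))
        rec = sg.generate_session(cfg)
        ev = rec.events_frame()
        stim = ev[ev["kind"] == "stimulus"]
        n = len(stim)
        assert n >= 5000
        frac = (stim["go_nogo"] == "nogo").mean()
        p = 1.0 / 9.0
        assert abs(frac - p) < 2.58 * np.sqrt(p * (1 - p) / n)

    def test_probe_interval_longer_than_block_yields_no_probe(self):
        cfg = tiny_config(block_duration=30.0, probe_interval_range=(35.0, 40.0))
        rec = sg.generate_session(cfg)
        assert not any(e.kind == "probe_onset" for e in rec.events)

    def test_behavior_rates_within_binomial_ci(self):
        cfg = sg.SessionConfig(seed=21, n_blocks=6, block_duration=150.0, state_dwell=40.0)
        rec = sg.generate_session(cfg)
        ev = rec.events_frame()
        stim = ev[ev["kind"] == "stimulus"].copy()
        stim["truth"] = [rec.truth_state_at(s) for s in stim["onset"]]
        for state in sg.STATES:
            bp = cfg.behavior_params[state]
            sub = stim[stim["truth"] == state]
            go = sub[sub["go_nogo"] == "go"]
            nogo = sub[sub["go_nogo"] == "nogo"]
            for frame, p, col_missing in ((go, bp.miss_prob, True), (nogo, bp.fa_prob, False)):
                n = len(frame)
                if n < 10:
                    continue
                obs = frame["rt_ms"].isna().mean() if col_missing else frame["rt_ms"].notna().mean()
                assert abs(obs - p) < 2.58 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_planted_p3b_contrast_recovers_amplitude(self):
        # quiet background, sparse SOA so baselines are uncontaminated
        quiet = {}
        for s, sp in sg.default_state_params().items():
            quiet[s] = dataclasses.replace(
                sp, noise_sd=0.3,
                band_power_map={b: (0.0, 0.0, 0.0, 0.0) for b in sg.BAND_BASE_AMP},
                linear_coupling=0.0, nonlinear_coupling=0.0)
        cfg = sg.SessionConfig(n_blocks=2, block_duration=150.0, seed=5,
                               soa_range=(1500.0, 1800.0), state_params=quiet,
                               state_dwell=30.0)
        rec = sg.generate_session(cfg)
        epochs = ms.baseline_correct(ex.truth_labeled_stimuli(rec))
        states = epochs.metadata["state_label"].to_numpy()
        assert {"ON", "MB"} <= set(states)
        rows = sg.channel_rows(cfg.n_channels)
        on = epochs.data[states == "ON"].mean(axis=0)[rows == 1].mean(axis=0)
        mb = epochs.data[states == "MB"].mean(axis=0)[rows == 1].mean(axis=0)
        t = epochs.times
        p3b = cfg.state_params["ON"]
        sel = (t >= p3b.p3b_latency / 1000.0) & (t <= (p3b.p3b_latency + p3b.p3b_duration) / 1000.0)
        peak = (on - mb)[sel].max()
        assert abs(peak - p3b.p3b_amp) / p3b.p3b_amp < 0.2

    def test_report_noise_generates_dr_answers(self):
        cfg = tiny_config(n_blocks=4, block_duration=150.0, report_noise=1.0,
                          state_dwell=20.0)
        rec = sg.generate_session(cfg)
        answers = [e.probe_answer for e in rec.events if e.kind == "probe_answer"]
        assert len(answers) >= 6
        assert set(answers) <= {"ON", "MW", "MB", "DR"}
        assert "DR" in answers          # noisy reports include "don't remember"

    def test_no_dr_without_report_noise(self, small_recording):
        answers = [e.probe_answer for e in small_recording.events
                   if e.kind == "probe_answer"]
        assert "DR" not in answers

    def test_front_back_fast_power_gradient(self, truth_epochs, small_recording):
        from mindstate import markers as mk
        mm = mk.compute_marker_matrix(truth_epochs)
        states = mm.metadata["state_label"].to_numpy()
        rows = sg.channel_rows(len(mm.channel_names))
        fast = mm.marker("psd_beta") + mm.marker("psd_gamma")
        contrast = fast[states == "MB"].mean(axis=0) - fast[states == "MW"].mean(axis=0)
        assert contrast[rows == 0].mean() > 0
        assert contrast[rows == 3].mean() < 0


class TestFixtureIO:
    def test_roundtrip_events_and_amplitude(self, tmp_path, small_recording):
        paths = sg.write_fixture(small_recording, tmp_path / "sess.edf")
        back = sg.read_fixture(paths["eeg"])
        # event tables identical
        a = small_recording.events_frame()
        b = back.events_frame()
        for kind in ("stimulus", "probe_onset"):
            xa = a[a["kind"] == kind].reset_index(drop=True)
            xb = b[b["kind"] == kind].reset_index(drop=True)
            assert np.array_equal(xa["onset"].to_numpy(), xb["onset"].to_numpy())
            if kind == "stimulus":
                assert (xa["stimulus_category"] == xb["stimulus_category"]).all()
                assert np.allclose(xa["rt_ms"].astype(float), xb["rt_ms"].astype(float),
                                   equal_nan=True)
        ans_a = a.loc[a["kind"] == "probe_answer", "probe_answer"].tolist()
        ans_b = b.loc[b["kind"] == "probe_answer", "probe_answer"].tolist()
        assert ans_a == ans_b
        # 16-bit quantization error: < 0.1 uV for a +-200 uV physical range
        err = np.abs(back.data - small_recording.data).max()
        phys = max(200.0, np.abs(small_recording.data).max())
        assert err < max(0.1, 2.0 * phys / 65534)

    def test_quantization_error_bound_at_200uV(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.uniform(-200, 200, size=(2, 500))
        rec = sg.ContinuousRecording(data=data, fs=250.0, channel_names=["a", "b"],
                                     channel_positions={}, events=[],
                                     truth_states=np.zeros(500, dtype=np.int8))
        paths = sg.write_fixture(rec, tmp_path / "q.edf")
        back = sg.read_fixture(paths["eeg"])
        assert np.abs(back.data[:, :500] - data).max() < 0.1

    def test_empty_events_session(self, tmp_path):
        rec = sg.ContinuousRecording(data=np.zeros((2, 250)), fs=250.0,
                                     channel_names=["a", "b"], channel_positions={},
                                     events=[], truth_states=np.zeros(250, dtype=np.int8))
        paths = sg.write_fixture(rec, tmp_path / "empty.edf")
        ev = pd.read_csv(paths["events"], sep="\t")
        pr = pd.read_csv(paths["probes"], sep="\t")
        assert len(ev) == 0 and len(pr) == 0

    def test_unsupported_extension(self, tmp_path, small_recording):
        with pytest.raises(FormatError):
            sg.write_fixture(small_recording, tmp_path / "sess.fif")
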