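"""Ground-truth generator: rates, trains, rendering, and presets."""

import math

import numpy as np
import pytest

from gravimea import synthdata as sd
from gravimea.phases import Phase, PhaseSchedule, analysis_windows, generation_segments


class TestSampleUnitRates:
    def test_degenerate_sigma_gives_median(self):
        rates = sd.sample_unit_rates(5, math.log(3.0), 0.0, seed=1)
        assert np.allclose(rates, 3.0)

    def test_sample_median_matches_closed_form(self):
        rates = sd.sample_unit_rates(10000, math.log(3.0), 0.5, seed=2)
        assert np.median(rates) == pytest.approx(3.0, rel=0.05)
        assert np.all(rates > 0)

    def test_deterministic_under_seed(self):
        a = sd.sample_unit_rates(100, 1.0, 0.4, seed=7)
        b = sd.sample_unit_rates(100, 1.0, 0.4, seed=7)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("n,sigma", [(0, 0.5), (-3, 0.5), (10, -0.1)])
    def test_invalid_parameters(self, n, sigma):
        with pytest.raises(ValueError):
            sd.sample_unit_rates(n, 1.0, sigma)


class TestGenerateSpikeTrain:
    def test_zero_rate_gives_empty_train(self):
        assert len(sd.generate_spike_train(0.0, duration=100.0, seed=1)) == 0

    def test_homogeneous_count_within_poisson_error(self):
        # 3 Hz for 600 s: mean 1800, allow 3 sigma
        t = sd.generate_spike_train(3.0, duration=600.0, seed=3)
        assert abs(len(t) - 1800) <= 3 * math.sqrt(1800)

    def test_refractory_never_violated(self):
        for seed in range(5):
            t = sd.generate_spike_train(
                30.0, duration=60.0, bursts=sd.BurstStructure(), refractory=0.002, seed=seed
            )
            assert np.all(np.diff(t) >= 0.002 - 1e-12)
            assert np.all(np.diff(t) > 0)

    def test_piecewise_rates_recovered(self):
        profile = [(0.0, 60.0, 2.0), (60.0, 120.0, 10.0)]
        t = sd.generate_spike_train(profile, seed=4)
        n1 = np.sum(t < 60.0)
        n2 = np.sum(t >= 60.0)
        assert abs(n1 - 120) <= 4 * math.sqrt(120)
        assert abs(n2 - 600) <= 4 * math.sqrt(600)

    def test_bursty_train_contains_detectable_bursts(self):
        from gravimea.bursts import detect_bursts

        t = sd.generate_spike_train(
            5.0, duration=120.0, bursts=sd.BurstStructure(), seed=5
        )
        assert len(detect_bursts(t)) > 10

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            sd.generate_spike_train(-1.0, duration=10.0)


class TestRenderRecording:
    def test_single_spike_noiseless_is_exact_template(self, single_phase_schedule):
        cfg = sd.SynthConfig(
            n_channels=4, n_units=1, empty_channel_fraction=0.0, noise_sigma=0.0,
            amplitude_sigma=0.0, sampling_rate=25000.0, seed=6, bursts=None,
        )
        truth = sd.build_ground_truth(cfg, single_phase_schedule)
        # replace with exactly one spike at 1.0 s
        u = truth.units[0]
        u.spike_times = np.array([1.0])
        rec = sd.render_recording(cfg, truth)
        row = rec.samples[rec.channel_ids.index(u.channel_id)]
        w, trough = sd.biphasic_template(u.amplitude, 25000.0)
        i0 = 25000 - trough
        assert np.allclose(row[i0 : i0 + len(w)], w)
        mask = np.ones(len(row), bool)
        mask[i0 : i0 + len(w)] = False
        assert np.all(row[mask] == 0)
        # all other channels silent
        for ci, cid in enumerate(rec.channel_ids):
            if cid != u.channel_id:
                assert np.all(rec.samples[ci] == 0)

    def test_empty_channel_noise_std(self, single_phase_schedule):
        cfg = sd.SynthConfig(
            n_channels=4, n_units=2, empty_channel_fraction=0.5,
            noise_sigma=4.0, sampling_rate=25000.0, seed=7,
        )
        rec, truth = sd.simulate_recording(cfg, single_phase_schedule)
        for ci, cid in enumerate(rec.channel_ids):
            if not truth.channel_has_unit[cid]:
                assert np.std(rec.samples[ci]) == pytest.approx(4.0, rel=0.05)

    def test_common_mode_shared_by_all_channels(self, single_phase_schedule):
        cfg = sd.SynthConfig(
            n_channels=5, n_units=2, empty_channel_fraction=0.0, noise_sigma=0.0,
            common_mode=sd.CommonMode(amplitude=15.0, frequency=50.0),
            sampling_rate=10000.0, seed=8, bursts=None,
        )
        rec, truth = sd.simulate_recording(cfg, single_phase_schedule)
        t = np.arange(rec.n_samples) / rec.sampling_rate
        expected = 15.0 * np.sin(2 * np.pi * 50.0 * t)
        med = np.median(rec.samples, axis=0)
        # the channel-wise median at each sample tracks the artifact
        assert np.corrcoef(med, expected)[0, 1] > 0.999

    def test_calibration_error_on_overrange_amplitude(self, single_phase_schedule):
        cfg = sd.SynthConfig(
            n_channels=4, n_units=1, empty_channel_fraction=0.0,
            amplitude_mu=5000.0, amplitude_sigma=0.0, noise_sigma=0.0, seed=9,
        )
        truth = sd.build_ground_truth(cfg, single_phase_schedule)
        with pytest.raises(sd.CalibrationError):
            sd.render_recording(cfg, truth)

    def test_bit_identical_under_same_seed(self, single_phase_schedule):
        cfg = sd.SynthConfig(n_channels=6, n_units=3, sampling_rate=5000.0, seed=11)
        rec1, truth1 = sd.simulate_recording(cfg, single_phase_schedule)
        rec2, truth2 = sd.simulate_recording(cfg, single_phase_schedule)
        assert np.array_equal(rec1.samples, rec2.samples)
        for u1, u2 in zip(truth1.units, truth2.units):
            assert np.array_equal(u1.spike_times, u2.spike_times)
            assert u1.phase_rates == u2.phase_rates


class TestGroundTruthInvariants:
    def test_spike_times_increasing_and_refractory(self, single_phase_schedule):
        cfg = sd.SynthConfig(n_channels=10, n_units=8, seed=12)
        truth = sd.build_ground_truth(cfg, single_phase_schedule)
        for u in truth.units:
            d = np.diff(u.spike_times)
            assert np.all(d > 0)
            assert np.all(d >= cfg.refractory - 1e-12)

    def test_empirical_rates_track_true_rates(self):
        sch = PhaseSchedule((Phase("a", 0, 60.0), Phase("b", 60.0, 120.0)), safety_margin=0.0)
        cfg = sd.SynthConfig(n_channels=30, n_units=25, seed=13)
        truth = sd.build_ground_truth(cfg, sch)
        ok = 0
        total = 0
        for u in truth.units:
            for w in truth.segments:
                r = u.phase_rates[w.label]
                t = u.spike_times
                emp = np.sum((t >= w.start) & (t < w.end)) / w.duration
                total += 1
                ok += abs(emp - r) <= 4 * math.sqrt(max(r, 1e-12) / w.duration) + 1e-9
        assert ok / total >= 0.95

    def test_unit_capacity_validation(self, single_phase_schedule):
        cfg = sd.SynthConfig(n_channels=4, n_units=9, empty_channel_fraction=0.0)
        with pytest.raises(ValueError):
            cfg.validate()


class TestMakePreset:
    def test_drop_schedule_full_scale(self):
        _, sch = sd.make_preset("drop", scale=1.0)
        durs = [p.duration for p in sch.phases]
        assert durs == pytest.approx([600.0, 4.7, 5.0, 600.0])
        assert sch.safety_margin == pytest.approx(0.150)

    def test_drop_short_phases_never_scaled(self):
        _, sch = sd.make_preset("drop", scale=0.1)
        durs = [p.duration for p in sch.phases]
        assert durs == pytest.approx([60.0, 4.7, 5.0, 60.0])

    def test_centrifuge_schedule_full_scale(self):
        _, sch = sd.make_preset("centrifuge_6g", scale=1.0)
        by_label = {p.label: p for p in sch.phases}
        assert by_label["ramp_up"].duration == pytest.approx(30.0)
        assert by_label["hyperG"].duration == pytest.approx(300.0)
        assert by_label["hyperG"].g_level == 6.0
        assert by_label["hyperG"].split and by_label["post"].split
        assert sch.safety_margin == pytest.approx(2.0)

    def test_drop_modulation_encodes_microgravity_effect(self):
        cfg, sch = sd.make_preset("drop", scale=0.1)
        cfg.n_units = 30
        cfg.seed = 14
        truth = sd.build_ground_truth(cfg, sch)
        lows = [u for u in truth.units if u.subgroup == "low"]
        mids = [u for u in truth.units if u.subgroup == "mid"]
        highs = [u for u in truth.units if u.subgroup == "high"]
        for u in lows + mids:
            assert u.phase_rates["microgravity"] == pytest.approx(u.baseline_rate * 4 / 3)
        signs = [np.sign(u.phase_rates["microgravity"] - u.baseline_rate) for u in highs]
        n_up = sum(1 for s in signs if s > 0)
        assert abs(n_up - len(highs) / 2) <= 1  # ~50/50 split

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            sd.make_preset("parabolic")

    def test_scale_bounds(self):
        with pytest.raises(ValueError):
            sd.make_preset("drop", scale=0.0)
        with pytest.raises(ValueError):
            sd.make_preset("drop", scale=1.5)


class TestScheduleWindows:
    def test_drop_microgravity_analysis_window(self):
        _, sch = sd.make_preset("drop", scale=1.0)
        win = {w.label: w for w in analysis_windows(sch)}["microgravity"]
        assert win.start == pytest.approx(600.15)
        assert win.end == pytest.approx(604.55)
        assert win.duration == pytest.approx(4.4)

    def test_centrifuge_split_windows(self):
        _, sch = sd.make_preset("centrifuge_6g", scale=1.0)
        wins = {w.label: w for w in analysis_windows(sch)}
        hyper = sch.phase("hyperG")
        assert wins["hyperG1"].start == pytest.approx(hyper.start + 2.0)
        assert wins["hyperG1"].duration == pytest.approx(56.0)
        assert wins["hyperG2"].end == pytest.approx(hyper.end - 2.0)
        assert {"baseline", "ramp_up", "hyperG1", "hyperG2", "ramp_down", "post1", "post2"} == set(
            wins
        )

    def test_generation_segments_tile_phases(self):
        _, sch = sd.make_preset("centrifuge_4g", scale=1.0)
        segs = generation_segments(sch)
        assert segs[0].start == 0.0
        for a, b in zip(segs[:-1], segs[1:]):
            assert b.start == pytest.approx(a.end)
        assert segs[-1].end == pytest.approx(sch.total_duration)
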