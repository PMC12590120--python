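"""Generator contracts: stimuli, burst schedules, gyroscope, forward-mixed EEG."""

import numpy as np
import pytest

from walkassr.motion import detect_turns, lowpass_yaw
from walkassr.preprocess import welch_spectrum
from walkassr.synth import (FRONTOCENTRAL, OCCIPITAL, SessionConfig,
                            StimulusConfig, generate_am_tone, schedule_bursts,
                            simulate_eeg, simulate_gyro, turn_apex_times)


class TestAmTone:
    def test_depth_zero_gives_pure_carrier(self):
        cfg = StimulusConfig(depth=0.0)
        s = generate_am_tone(cfg, "left", 0.5)
        env = np.abs(s[np.abs(s) > 0.99 * np.max(np.abs(s))])
        assert np.allclose(np.max(np.abs(s)), 1.0, atol=1e-3)
        # analytic check: no modulation term at all
        t = np.arange(len(s)) / cfg.audio_fs
        assert np.allclose(s, np.sin(2 * np.pi * 1000.0 * t))

    def test_full_depth_envelope_extrema(self):
        s = generate_am_tone(StimulusConfig(depth=1.0), "right", 1.0)
        # envelope of (1 + sin) ranges over [0, 2]
        assert np.max(np.abs(s)) == pytest.approx(2.0, abs=0.01)
        # near envelope minima the waveform is (locally) almost silent
        cfg = StimulusConfig()
        t = np.arange(len(s)) / cfg.audio_fs
        env = 1 + np.sin(2 * np.pi * 41.0 * t)
        assert np.max(np.abs(s[env < 1e-3])) < 5e-3

    @pytest.mark.parametrize("side,f_mod", [("left", 39.0), ("right", 41.0)])
    def test_envelope_spectrum_peaks_at_modulation_rate(self, side, f_mod):
        cfg = StimulusConfig()
        s = generate_am_tone(cfg, side, 1.0)
        env = np.abs(s)  # rectified signal carries the envelope
        spec = np.abs(np.fft.rfft(env - env.mean()))
        freqs = np.fft.rfftfreq(len(env), 1 / cfg.audio_fs)
        low = (freqs > 5) & (freqs < 500)
        assert freqs[low][np.argmax(spec[low])] == pytest.approx(f_mod, abs=1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_am_tone(StimulusConfig(), "up", 1.0)
        with pytest.raises(ValueError):
            generate_am_tone(StimulusConfig(), "left", 0.0)
        with pytest.raises(ValueError):
            StimulusConfig(depth=1.5)
        with pytest.raises(ValueError):
            StimulusConfig(mod_left_hz=40, mod_right_hz=40)


class TestBurstSchedule:
    def test_counts_and_gap_range(self):
        sch = schedule_bursts(120.0, 8, seed=4)
        for kind in ("left", "right", "central"):
            on = np.array(sch.onsets(kind))
            assert len(on) == 8
            gaps = np.diff(on)
            assert np.all(gaps >= 3.0) and np.all(gaps <= 7.0)

    def test_seed_determinism(self):
        a = schedule_bursts(200.0, 16, seed=9)
        b = schedule_bursts(200.0, 16, seed=9)
        assert a.events == b.events
        c = schedule_bursts(200.0, 16, seed=10)
        assert a.events != c.events

    def test_gap_mean_matches_uniform_3_7(self):
        # Monte-Carlo oracle: mean of U(3,7) is 5
        gaps = []
        for seed in range(25):
            sch = schedule_bursts(3000.0, 400, seed=seed, kinds=("left",))
            gaps.extend(np.diff(sch.onsets("left")))
        assert 4.9 <= np.mean(gaps) <= 5.1
        assert len(gaps) >= 9000

    def test_infeasible_duration_raises(self):
        with pytest.raises(ValueError):
            schedule_bursts(20.0, 8, seed=0)
        with pytest.raises(ValueError):
            schedule_bursts(100.0, 0, seed=0)


class TestGyro:
    def test_noiseless_apices_at_analytic_times(self):
        cfg = SessionConfig(movement_state="walk", n_laps=4, seed=0,
                            gyro_noise_dps=0.0, gyro_ripple_dps=0.0)
        m = simulate_gyro(cfg)
        left, right = turn_apex_times(cfg)
        from scipy.signal import find_peaks
        pos, _ = find_peaks(m.yaw, height=0.9 * cfg.gyro_peak_dps)
        neg, _ = find_peaks(-m.yaw, height=0.9 * cfg.gyro_peak_dps)
        assert len(pos) == 4 and len(neg) == 4
        assert np.allclose(pos / m.fs, left, atol=1.5 / m.fs)
        assert np.allclose(neg / m.fs, right, atol=1.5 / m.fs)

    def test_default_noise_turns_recovered(self):
        cfg = SessionConfig(movement_state="walk", n_laps=6, seed=14)
        turns = detect_turns(lowpass_yaw(simulate_gyro(cfg)))
        left, right = turn_apex_times(cfg)
        det_l = [t.apex_time_s for t in turns if t.direction == "left"]
        det_r = [t.apex_time_s for t in turns if t.direction == "right"]
        assert np.allclose(sorted(det_l), left, atol=0.25)
        assert np.allclose(sorted(det_r), right, atol=0.25)

    def test_standing_has_no_turns(self):
        cfg = SessionConfig(movement_state="stand", n_laps=4, seed=3)
        m = lowpass_yaw(simulate_gyro(cfg))
        assert np.max(np.abs(m.yaw)) < 5.0
        assert detect_turns(m, magnitude_threshold=10.0) == []

    def test_yaw_sign_convention_flippable(self):
        cfg = SessionConfig(movement_state="walk", n_laps=2, seed=0,
                            gyro_noise_dps=0.0, gyro_ripple_dps=0.0,
                            left_positive_yaw=False)
        m = simulate_gyro(cfg)
        left, _ = turn_apex_times(cfg)
        i = int(round(left[0] * m.fs))
        assert m.yaw[i] < 0  # left turn now negative


class TestEeg:
    def test_event_integrity(self):
        cfg = SessionConfig(movement_state="stand", n_laps=4, seed=5)
        sch = schedule_bursts(cfg.duration_s, 5, seed=6)
        rec = simulate_eeg(cfg, schedule=sch)
        for on, kind in sch.events:
            matches = [e for e in rec.events
                       if e.label == f"burst_{kind}"
                       and e.sample == int(round(on * rec.fs))]
            assert len(matches) == 1
        n_burst_events = sum(1 for e in rec.events if e.label.startswith("burst"))
        assert n_burst_events == len(sch.events)

    def test_seed_determinism(self):
        cfg = SessionConfig(movement_state="stand", n_laps=2, seed=8)
        a = simulate_eeg(cfg)
        b = simulate_eeg(cfg)
        assert np.array_equal(a.data, b.data)
        c = simulate_eeg(cfg, seed=9)
        assert not np.array_equal(a.data, c.data)

    def test_noiseless_welch_power_matches_analytic_sinusoid(self, quiet_config):
        # closed form: a sinusoid of amplitude A has total power A²/2;
        # silence the 41 Hz source so its spectral leakage cannot bleed in
        cfg = quiet_config
        cfg.assr_amp = {s: {39.0: a[39.0], 41.0: 0.0}
                        for s, a in cfg.assr_amp.items()}
        rec = simulate_eeg(cfg)
        topo = np.array(rec.meta["truth"]["topo_assr"])
        labels = rec.channel_labels
        w = np.mean([topo[labels.index(ch)] for ch in FRONTOCENTRAL])
        amp39 = rec.meta["truth"]["assr_amp"]["39.0"] * w
        fc = rec.get(FRONTOCENTRAL).mean(axis=0)
        spec = welch_spectrum(fc, rec.fs)
        df = spec.freqs[1] - spec.freqs[0]
        band = (spec.freqs >= 36.0) & (spec.freqs <= 42.0)
        measured = np.sum(spec.power[band]) * df
        assert measured == pytest.approx(amp39 ** 2 / 2, rel=0.05)

    def test_zero_assr_amplitude_leaves_no_clear_peak(self):
        # with silent sources, any residual Welch-noise bump must stay below
        # the 0.10 log10-unit "clear ASSR" selection threshold
        from walkassr.specparam import fit_parameterized, parameterized_power
        zero = {39.0: 0.0, 41.0: 0.0}
        for seed in (2, 3):
            cfg = SessionConfig(movement_state="stand", n_laps=8, seed=seed,
                                assr_amp={"stand": zero, "step": zero,
                                          "walk": zero})
            rec = simulate_eeg(cfg)
            fc = rec.get(FRONTOCENTRAL).mean(axis=0)
            ps = fit_parameterized(welch_spectrum(fc, rec.fs))
            assert parameterized_power(ps, 39.0, tol=0.5) < 0.10
            assert parameterized_power(ps, 41.0, tol=0.5) < 0.10

    def test_alpha_state_ordering_propagates_to_occipital_power(self):
        # configured alpha_amp(stand) > alpha_amp(walk) must show in measured
        # Welch alpha power on O1/O2 for nearly every seed
        correct = 0
        n_seeds = 20
        for seed in range(n_seeds):
            powers = {}
            for state in ("stand", "walk"):
                cfg = SessionConfig(movement_state=state, n_laps=2, seed=seed)
                rec = simulate_eeg(cfg)
                occ = rec.get(OCCIPITAL).mean(axis=0)
                spec = welch_spectrum(occ, rec.fs)
                powers[state] = spec.band_mean(8.0, 14.0)
            correct += powers["stand"] > powers["walk"]
        assert correct >= 0.95 * n_seeds

    def test_missing_motion_with_lateralization_raises(self):
        cfg = SessionConfig(movement_state="walk", n_laps=2, lateral_gain=1.5)
        with pytest.raises(ValueError):
            simulate_eeg(cfg)

    def test_overlong_schedule_rejected(self):
        cfg = SessionConfig(movement_state="stand", n_laps=2, seed=1)
        sch = schedule_bursts(cfg.duration_s * 3, 10, seed=2)
        with pytest.raises(ValueError):
            simulate_eeg(cfg, schedule=sch)
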