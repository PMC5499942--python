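"""Generators: determinism, ground-truth closure, closed-loop recovery."""

import numpy as np
import pytest

from escapekit import kinematics as kin
from escapekit.bioluminescence import PhotonTrace, detect_signal, estimate_baseline, process_trace
from escapekit.calcium import classify_active, recruitment_summary
from escapekit.ephys import compute_lag, detect_epsc, detect_spike_ttp
from escapekit.synthetic import (
    gen_calcium_population,
    gen_ephys_sweeps,
    gen_photon_train,
    gen_tail_trace,
    motor_drive,
)


class TestDeterminism:
    def test_tail_trace_bit_identical_on_same_seed(self):
        a, _ = gen_tail_trace("escape", seed=5, trial=3)
        b, _ = gen_tail_trace("escape", seed=5, trial=3)
        assert np.array_equal(a.angle, b.angle)
        assert np.array_equal(a.head_xy, b.head_xy)
        c, _ = gen_tail_trace("escape", seed=6, trial=3)
        assert not np.array_equal(a.angle, c.angle)

    def test_photon_train_bit_identical_on_same_seed(self):
        d = motor_drive("escape", 2000, 500)
        a, _ = gen_photon_train(d, seed=2, trial=1)
        b, _ = gen_photon_train(d, seed=2, trial=1)
        assert np.array_equal(a, b)

    def test_calcium_population_bit_identical_on_same_seed(self):
        ca, *_ = gen_calcium_population(seed=4)
        cb, *_ = gen_calcium_population(seed=4)
        for x, y in zip(ca, cb):
            assert np.array_equal(x.fluorescence, y.fluorescence)

    def test_ephys_sweeps_bit_identical_on_same_seed(self):
        (cc_a, vc_a, _) = gen_ephys_sweeps(seed=8)
        (cc_b, vc_b, _) = gen_ephys_sweeps(seed=8)
        assert np.array_equal(cc_a.trace, cc_b.trace)
        assert np.array_equal(vc_a.trace, vc_b.trace)


class TestTailGenerator:
    def test_noiseless_escape_classified_as_escape(self):
        tr, _ = gen_tail_trace("escape", seed=0, noise_sd_deg=0.0, jitter=False)
        sm = kin.smooth_tail_angle(tr, 3)
        bout = kin.detect_bout(sm)
        peaks = kin.detect_peaks(sm, bout)
        assert kin.classify_maneuver(bout, peaks) == "escape"

    def test_noiseless_swim_classified_as_slow_swim(self):
        tr, _ = gen_tail_trace("slow_swim", seed=0, noise_sd_deg=0.0, jitter=False)
        sm = kin.smooth_tail_angle(tr, 3)
        bout = kin.detect_bout(sm)
        peaks = kin.detect_peaks(sm, bout)
        assert kin.classify_maneuver(bout, peaks) == "slow_swim"

    def test_default_escape_passes_exclusion_and_swim_fails_weak_peak(self):
        esc, _ = gen_tail_trace("escape", seed=3, jitter=False)
        sm = kin.smooth_tail_angle(esc, 3)
        peaks = kin.detect_peaks(sm, kin.detect_bout(sm))
        kept, _ = kin.exclude_trial(sm, peaks)
        assert kept
        swim, _ = gen_tail_trace("slow_swim", seed=3, jitter=False)
        sm = kin.smooth_tail_angle(swim, 3)
        peaks = kin.detect_peaks(sm, kin.detect_bout(sm))
        kept, reason = kin.exclude_trial(sm, peaks)
        assert not kept and reason == "weak_first_peak"

    def test_transition_matches_detected_fast_slow_boundary(self):
        tr, gt = gen_tail_trace("escape", seed=0, noise_sd_deg=0.0, jitter=False)
        sm = kin.smooth_tail_angle(tr, 3)
        bout = kin.detect_bout(sm)
        peaks = kin.detect_peaks(sm, bout)
        frames = np.array([f for f, _ in peaks]) - tr.stim_frame
        comp = kin.split_fast_slow(np.diff(frames), tr.fps)
        i = comp.labels.index("slow")
        detected = frames[i]
        assert abs(detected - gt.derived["transition_frames_post_stim"]) <= np.diff(frames)[i]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            gen_tail_trace("burst", seed=0)


class TestPhotonGenerator:
    def test_zero_drive_gives_homogeneous_baseline(self):
        counts, gt = gen_photon_train(np.zeros(2000), seed=1)
        trace = PhotonTrace(counts, 1000)
        est = estimate_baseline(trace)
        assert est == pytest.approx(0.5, abs=0.3)

    def test_zero_gain_zero_baseline_gives_empty_train(self):
        counts, _ = gen_photon_train(np.zeros(1000), seed=1, baseline_rate=0.0, gain=0.0)
        assert counts.sum() == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_photon_train(np.zeros(100), seed=0, baseline_rate=-0.1)

    def test_doubling_gain_doubles_detected_amplitude(self):
        def mean_amp(gain):
            amps = []
            for trial in range(25):
                d = motor_drive("escape", 3000, 500)
                counts, _ = gen_photon_train(d, seed=9, trial=trial, gain=gain)
                proc, _, sb = process_trace(PhotonTrace(counts, 500))
                sig = detect_signal(proc, sb)
                amps.append(sig.amplitude)
            return np.mean(amps)

        assert mean_amp(60.0) / mean_amp(30.0) == pytest.approx(2.0, rel=0.1)

    def test_escape_amplitude_exceeds_swim_amplitude(self):
        # motor drive contrast >= 3x must always show up in the detected
        # amplitudes (escapes ~30 vs swims ~4 photons/10 ms)
        def amps(kind):
            out = []
            for trial in range(10):
                d = motor_drive(kind, 3000, 500)
                counts, _ = gen_photon_train(d, seed=13, trial=trial, stim_ms=500)
                proc, _, sb = process_trace(PhotonTrace(counts, 500))
                sig = detect_signal(proc, sb)
                out.append(sig.amplitude if sig else 0.0)
            return np.mean(out)

        assert amps("escape") > amps("slow_swim")


class TestCalciumGenerator:
    def test_zero_noise_zero_contamination_is_perfectly_recovered(self):
        for seed in range(5):
            cells, bgv, bgd, events, gt = gen_calcium_population(
                seed=seed, noise_sd=0.0, contamination_dff=0.0
            )
            for ev in events:
                flags = classify_active(cells, bgv, bgd, ev)
                truth = gt.derived["active_by_event"][ev.event_id]
                got = {int(r[3:]) for r, f in flags.items() if f}
                assert got == truth

    def test_dorsoventral_ordering_holds_on_every_seed(self):
        for seed in range(10):
            *_, gt = gen_calcium_population(seed=seed)
            dv = gt.derived["dv_norm"]
            swim = sorted(gt.derived["swim_cells"])
            esc_only = sorted(gt.derived["escape_cells"] - gt.derived["swim_cells"])
            assert dv[esc_only].mean() > dv[swim].mean()

    def test_invalid_population_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_calcium_population(seed=0, n_cells=0)
        with pytest.raises(ValueError):
            gen_calcium_population(seed=0, n_swim_recruited=70)


class TestEphysGenerator:
    def test_noiseless_defaults_recover_printed_latencies_and_lag(self):
        cc, vc, _ = gen_ephys_sweeps(seed=0, noise_sd_cc_mv=0.0, noise_sd_vc_pa=0.0)
        ttps = [detect_spike_ttp(cc, o) for o in cc.pulse_onsets_ms]
        epscs = [detect_epsc(vc, o) for o in vc.pulse_onsets_ms]
        assert np.mean(ttps) == pytest.approx(2.80, abs=0.05)
        onsets = [o for o, _ in epscs]
        assert np.mean(onsets) == pytest.approx(3.71, abs=0.15)
        lag = compute_lag(ttps, onsets)
        assert lag == pytest.approx(0.91, abs=0.15)

    def test_noise_only_sweeps_detect_nothing(self):
        cc, vc, _ = gen_ephys_sweeps(seed=1, spike_amp_mv=0.0, epsc_amp_pa=0.0)
        assert all(detect_spike_ttp(cc, o) is None for o in cc.pulse_onsets_ms)
        assert all(detect_epsc(vc, o) is None for o in vc.pulse_onsets_ms)

    def test_latency_jitter_shows_up_in_sample_spread(self):
        cc, vc, gt = gen_ephys_sweeps(
            seed=2, n_stim=100, spike_jitter_ms=0.29, epsc_jitter_ms=0.19
        )
        ttps = np.array([detect_spike_ttp(cc, o) for o in cc.pulse_onsets_ms])
        onsets = np.array([detect_epsc(vc, o)[0] for o in vc.pulse_onsets_ms])
        assert np.std(ttps, ddof=1) == pytest.approx(0.29, rel=0.30)
        assert np.std(onsets, ddof=1) == pytest.approx(0.19, rel=0.30)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_ephys_sweeps(seed=0, spike_latency_ms=-1.0)
        with pytest.raises(ValueError):
            gen_ephys_sweeps(seed=0, epsc_amp_pa=-5.0)
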