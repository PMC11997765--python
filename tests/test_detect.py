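"""Detectors: filter responses, Hilbert detection, QC, spike stand-in,
event matching."""

import numpy as np
import pytest
from scipy.signal import hilbert

from hfomark.detect import (
    FR_BAND,
    RIPPLE_BAND,
    HfoDetectorParams,
    SpikeDetectorParams,
    accepted,
    bandpass,
    detect_hfo_channel,
    detect_hfos,
    detect_spikes_standin,
    match_events,
    preprocess_for_spikes,
    qc_hfo,
)
from hfomark.synth import SynthParams, synth_background, synth_event_waveform
from hfomark.types import Event, EventType, QcStatus, Recording, ValidationError

FS = 2000.0


def _sine(freq, duration=5.0, amp=1.0):
    t = np.arange(int(duration * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def _noise_recording(seed, n_channels=4, duration=30.0, alpha=1.0):
    return synth_background(
        SynthParams(
            n_channels=n_channels, duration=duration, seed=seed,
            background_exponent=alpha, n_soz_channels=0, n_resected_channels=0,
        )
    )


class TestBandpass:
    def test_in_band_sine_retained(self):
        x = _sine(120.0)
        y = bandpass(x, RIPPLE_BAND, FS)
        core = slice(int(FS), int(4 * FS))
        assert np.std(y[core]) / np.std(x[core]) >= 0.95

    def test_out_of_band_sine_suppressed(self):
        x = _sine(120.0)
        y = bandpass(x, FR_BAND, FS)
        core = slice(int(FS), int(4 * FS))
        assert np.std(y[core]) / np.std(x[core]) <= 0.05

    def test_zero_phase_impulse_symmetry(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        y = bandpass(x, RIPPLE_BAND, FS)
        assert np.allclose(y[2000 - 500 : 2000], y[2000 + 500 : 2000 : -1], atol=1e-9)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            bandpass(np.zeros(4000), (80.0, 1100.0), FS)


class TestPreprocess:
    def test_dc_removed(self):
        rec = Recording(np.full((3, 4000), 100.0) + np.arange(3)[:, None], FS, list("abc"))
        out = preprocess_for_spikes(rec)
        assert np.all(np.abs(out.signal.mean(axis=1)) < 1e-6 * 100)

    def test_60hz_suppressed(self):
        sig = np.vstack([_sine(60.0, 2.0), -_sine(60.0, 2.0)])
        rec = Recording(sig, FS, ["a", "b"])
        out = preprocess_for_spikes(rec)
        assert np.std(out.signal[0]) < 0.05 * np.std(sig[0])

    def test_200hz_suppressed(self):
        sig = np.vstack([_sine(200.0, 2.0), -_sine(200.0, 2.0)])
        out = preprocess_for_spikes(Recording(sig, FS, ["a", "b"]))
        assert np.std(out.signal[0]) < 0.05 * np.std(sig[0])

    def test_single_channel_needs_car_opt_out(self):
        rec = Recording(_sine(10.0, 2.0)[None, :], FS, ["a"])
        with pytest.raises(ValidationError):
            preprocess_for_spikes(rec)
        out = preprocess_for_spikes(rec, car=False)
        assert out.n_channels == 1


def _inject_burst(x, f0, n_cycles, snr, at, band):
    amp = snr * np.mean(np.abs(hilbert(bandpass(x, band, FS))))
    etype = EventType.RIPPLE if band == RIPPLE_BAND else EventType.FAST_RIPPLE
    w = synth_event_waveform(etype, f0, n_cycles, amp, FS)
    c = int(at * FS) - len(w) // 2
    x[c : c + len(w)] += w
    return x


class TestHfoDetection:
    def test_noise_only_yields_no_events(self):
        hits = 0
        for seed in range(100):
            rec = _noise_recording(seed, n_channels=1, duration=60.0, alpha=0.0)
            evs = detect_hfo_channel(rec.signal[0], FS, HfoDetectorParams())
            hits += len(evs) > 0
        assert hits <= 5

    def test_injected_burst_detected_with_accurate_peak(self):
        rec = _noise_recording(7, n_channels=1, duration=20.0)
        x = _inject_burst(rec.signal[0], 120.0, 8, 5.0, 10.0, RIPPLE_BAND)
        evs = detect_hfo_channel(x, FS, HfoDetectorParams())
        assert len(evs) == 1
        assert abs(evs[0].peak_time - 10.0) < 0.010
        assert 80 <= evs[0].peak_frequency <= 250

    def test_three_cycle_burst_rejected(self):
        rec = _noise_recording(8, n_channels=1, duration=20.0)
        x = _inject_burst(rec.signal[0], 120.0, 3, 5.0, 10.0, RIPPLE_BAND)
        evs = detect_hfo_channel(x, FS, HfoDetectorParams())
        assert all(abs(ev.peak_time - 10.0) > 0.05 for ev in evs)

    def test_threshold_monotonicity(self):
        rec = _noise_recording(9, n_channels=1, duration=30.0)
        x = rec.signal[0]
        for at in (5.0, 12.0, 21.0):
            _inject_burst(x, 140.0, 8, 6.0, at, RIPPLE_BAND)
        counts = [
            len(detect_hfo_channel(x, FS, HfoDetectorParams(threshold_sd=sd)))
            for sd in (2.0, 3.0, 5.0, 8.0, 12.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self):
        rec = _noise_recording(10, n_channels=1, duration=20.0)
        x = _inject_burst(rec.signal[0], 150.0, 8, 6.0, 10.0, RIPPLE_BAND)
        shift = 400  # samples
        evs0 = detect_hfo_channel(x, FS, HfoDetectorParams())
        evs1 = detect_hfo_channel(np.roll(x, shift), FS, HfoDetectorParams())
        assert len(evs0) == len(evs1) == 1
        assert evs1[0].peak_time - evs0[0].peak_time == pytest.approx(
            shift / FS, abs=2 / FS
        )

    def test_short_segment_rejected(self):
        with pytest.raises(ValidationError):
            detect_hfo_channel(np.zeros(500), FS, HfoDetectorParams())


class TestQc:
    def test_clean_burst_accepted(self):
        rec = _noise_recording(11, n_channels=1, duration=20.0)
        x = _inject_burst(rec.signal[0], 300.0, 8, 6.0, 10.0, FR_BAND)
        evs = detect_hfo_channel(x, FS, HfoDetectorParams(band=FR_BAND))
        assert len(evs) >= 1
        ev = min(evs, key=lambda e: abs(e.peak_time - 10.0))
        assert qc_hfo(ev, x, FS, FR_BAND) is QcStatus.ACCEPTED

    # artifacts are fed through a permissive detector configuration so
    # that candidate events exist for QC to classify (the default
    # oscillation/duration rules already reject most filter ringing)
    _PERMISSIVE = dict(min_oscillations=1, min_duration_ms=0.0)

    def test_step_discontinuity_rejected_as_gibbs(self):
        rec = _noise_recording(12, n_channels=1, duration=20.0)
        x = rec.signal[0]
        x[int(10 * FS):] += 40 * np.std(x)  # sharp step -> filter ringing
        evs = detect_hfo_channel(
            x, FS, HfoDetectorParams(band=RIPPLE_BAND, **self._PERMISSIVE)
        )
        near = [e for e in evs if abs(e.peak_time - 10.0) < 0.05]
        assert near, "step ringing should trigger the permissive detector"
        for ev in near:
            assert qc_hfo(ev, x, FS, RIPPLE_BAND) is QcStatus.REJECTED_GIBBS

    def test_broadband_click_rejected(self):
        rec = _noise_recording(13, n_channels=1, duration=20.0)
        x = rec.signal[0]
        x[int(10 * FS)] += 60 * np.std(x)  # single-sample impulse
        evs = detect_hfo_channel(
            x, FS, HfoDetectorParams(band=RIPPLE_BAND, **self._PERMISSIVE)
        )
        near = [e for e in evs if abs(e.peak_time - 10.0) < 0.05]
        assert near, "broadband click should trigger the permissive detector"
        for ev in near:
            assert qc_hfo(ev, x, FS, RIPPLE_BAND) in (
                QcStatus.REJECTED_GIBBS,
                QcStatus.REJECTED_BLOB,
            )

    def test_qc_is_deterministic(self):
        rec = _noise_recording(14, n_channels=1, duration=20.0)
        x = _inject_burst(rec.signal[0], 130.0, 8, 6.0, 10.0, RIPPLE_BAND)
        (ev,) = detect_hfo_channel(x, FS, HfoDetectorParams())
        assert qc_hfo(ev, x, FS, RIPPLE_BAND) is qc_hfo(ev, x, FS, RIPPLE_BAND)


class TestSpikeStandin:
    def test_flat_signal_no_events(self):
        rec = Recording(np.zeros((2, 8000)), FS, ["a", "b"])
        assert detect_spikes_standin(rec) == []

    def test_recovery_on_injected_spikes(self, detection_patient_params):
        from hfomark.synth import synth_patient

        rec, events, _ = synth_patient(detection_patient_params(21))
        ref = [e for e in events if e.event_type is EventType.SPIKE]
        det = detect_spikes_standin(preprocess_for_spikes(rec))
        sens, prec, _ = match_events(det, ref, 100)
        assert sens >= 0.9
        assert prec >= 0.9

    def test_infinite_threshold_finds_nothing(self, detection_patient_params):
        from hfomark.synth import synth_patient

        rec, _, _ = synth_patient(detection_patient_params(22))
        det = detect_spikes_standin(
            preprocess_for_spikes(rec), SpikeDetectorParams(z_threshold=np.inf)
        )
        assert det == []


def _spike_at(ch, t):
    return Event(ch, t - 0.02, t + 0.02, EventType.SPIKE, peak_time=t)


class TestMatchEvents:
    def test_identical_lists_are_perfect(self):
        ref = [_spike_at("a", float(t)) for t in range(5)]
        sens, prec, pairs = match_events(ref, ref, 100)
        assert sens == prec == 1.0
        assert len(pairs) == 5

    def test_spurious_detections_cost_precision(self):
        ref = [_spike_at("a", float(t)) for t in range(10)]
        det = ref + [_spike_at("a", 100.0 + t) for t in range(5)]
        sens, prec, _ = match_events(det, ref, 100)
        assert sens == 1.0
        assert prec == pytest.approx(10 / 15)

    def test_shift_beyond_tolerance_matches_nothing(self):
        ref = [_spike_at("a", float(t)) for t in range(5)]
        det = [_spike_at("a", t + 0.2) for t in range(5)]
        sens, _, _ = match_events(det, ref, 100)
        assert sens == 0.0

    def test_matching_is_one_to_one(self):
        ref = [_spike_at("a", 1.0)]
        det = [_spike_at("a", 1.01), _spike_at("a", 0.99)]
        sens, prec, pairs = match_events(det, ref, 100)
        assert len(pairs) == 1
        assert sens == 1.0
        assert prec == 0.5

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValidationError):
            match_events([], [], -1.0)


def test_hfo_recovery_on_synthetic_patients(detection_patient_params):
    """Injected 8-cycle bursts at SNR 5: detection + QC recovers them."""
    from hfomark.synth import synth_patient

    tot = {"sens_r": [], "prec_r": [], "sens_f": [], "prec_f": []}
    for seed in (31, 32):
        rec, events, _ = synth_patient(detection_patient_params(seed))
        ref_r = [e for e in events if e.event_type is EventType.RIPPLE]
        ref_f = [e for e in events if e.event_type is EventType.FAST_RIPPLE]
        det_r = accepted(detect_hfos(rec, HfoDetectorParams(band=RIPPLE_BAND)))
        det_f = accepted(detect_hfos(rec, HfoDetectorParams(band=FR_BAND)))
        s, p, _ = match_events(det_r, ref_r, 50)
        tot["sens_r"].append(s), tot["prec_r"].append(p)
        s, p, _ = match_events(det_f, ref_f, 50)
        tot["sens_f"].append(s), tot["prec_f"].append(p)
    for key, vals in tot.items():
        assert np.mean(vals) >= 0.9, (key, vals)
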