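"""Event detection: Hilbert-envelope HFO detector, automated QC, and a
stand-in spike detector.

HFO candidates are maximal runs where the analytic-signal envelope of
the band-passed trace exceeds ``mean + threshold_sd * SD`` of the
envelope; nearby runs merge, short or under-oscillating runs are
discarded. QC mirrors visual review practice: accepted events show an
isolated spectral peak inside the band ("island") or at least four
oscillations in the filtered trace, and are rejected when filter
ringing from a sharp transient (Gibbs phenomenon) explains them.

The spike detector is a deliberately simple envelope z-score detector
in a 10–60 Hz sharp-activity band. It is not equivalent to commercial
clinical detectors; externally produced spike annotations can be
imported instead (see :func:`hfomark.io.read_event_table`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .types import (
    Event,
    EventType,
    QcStatus,
    Recording,
    ValidationError,
)

RIPPLE_BAND = (80.0, 250.0)
FR_BAND = (250.0, 500.0)


@dataclass
class HfoDetectorParams:
    """Hilbert-detector settings for one band."""

    band: tuple[float, float] = RIPPLE_BAND
    threshold_sd: float = 5.0
    boundary_sd: float = 2.0  # event edges delimited at this lower level
    min_oscillations: int = 4
    # default duration floor: min_oscillations cycles at the band's
    # upper edge (16 ms for 80-250 Hz, 8 ms for 250-500 Hz)
    min_duration_ms: float | None = None
    merge_gap_ms: float = 10.0
    robust: bool = False  # median/MAD envelope statistics instead of mean/SD

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 < lo < hi):
            raise ValidationError("band must satisfy 0 < low < high")
        if self.min_oscillations < 1:
            raise ValidationError("min_oscillations must be >= 1")


@dataclass
class QcParams:
    island_prominence_ratio: float = 2.0  # interior peak power / band-edge power
    gibbs_z_threshold: float = 6.0  # max |first difference| z-score in raw trace


@dataclass
class SpikeDetectorParams:
    bandpass: tuple[float, float] = (1.0, 70.0)
    notch_hz: float = 60.0
    sharp_band: tuple[float, float] = (10.0, 60.0)  # detection sub-band
    z_threshold: float = 6.0
    refractory_ms: float = 200.0
    min_duration_ms: float = 20.0
    max_duration_ms: float = 200.0


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def bandpass(
    x: np.ndarray, band: tuple[float, float], sampling_rate: float
) -> np.ndarray:
    """Zero-phase FIR band-pass; event times are not shifted.

    A symmetric (linear-phase) window-design kernel applied once via
    FFT convolution in 'same' mode: the symmetric kernel centred on
    each sample makes the filter exactly zero-phase.
    """
    lo, hi = band
    nyq = sampling_rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValidationError(f"band {band} outside (0, Nyquist={nyq})")
    transition = max(4.0, 0.15 * lo)  # Hz
    numtaps = int(3.3 * sampling_rate / transition) | 1
    numtaps = min(numtaps, (len(x) // 2) * 2 - 1)
    if numtaps < 9:
        raise ValidationError("signal too short for the requested band")
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=sampling_rate)
    return sps.fftconvolve(x, taps, mode="same")


def notch(x: np.ndarray, freq: float, sampling_rate: float, q: float = 5.0) -> np.ndarray:
    b, a = sps.iirnotch(freq, q, fs=sampling_rate)
    return sps.filtfilt(b, a, x)


def preprocess_for_spikes(
    recording: Recording, params: SpikeDetectorParams | None = None, car: bool = True
) -> Recording:
    """Common average reference, DC removal, 1–70 Hz band-pass, 60 Hz notch."""
    params = params or SpikeDetectorParams()
    if recording.sampling_rate <= 2 * params.bandpass[1]:
        raise ValidationError("sampling rate too low for the spike band")
    sig = recording.signal.copy()
    if car:
        if recording.n_channels < 2:
            raise ValidationError(
                "common average reference needs >= 2 channels (pass car=False to skip)"
            )
        sig = sig - sig.mean(axis=0, keepdims=True)
    sig = sig - sig.mean(axis=1, keepdims=True)
    out = np.empty_like(sig)
    for i in range(sig.shape[0]):
        y = bandpass(sig[i], params.bandpass, recording.sampling_rate)
        out[i] = notch(y, params.notch_hz, recording.sampling_rate)
    return Recording(
        signal=out,
        sampling_rate=recording.sampling_rate,
        channel_ids=list(recording.channel_ids),
        start_time=recording.start_time,
    )


# ---------------------------------------------------------------------------
# HFO detection
# ---------------------------------------------------------------------------

def _count_oscillations(
    filtered: np.ndarray, env_max: float, duration_s: float, peak_freq: float
) -> int:
    """Oscillation cycles within the event.

    Rectified-signal peaks above a quarter of the event's envelope
    maximum count half-waves (two per cycle); the tally is capped by
    the number of cycles the event's duration can span at its peak
    frequency, so brief ringing cannot masquerade as a long burst.
    """
    peaks, _ = sps.find_peaks(np.abs(filtered), height=0.25 * env_max)
    half_wave_pairs = round(len(peaks) / 2)
    spanned_cycles = int(np.ceil(duration_s * peak_freq - 1e-9))
    return int(min(half_wave_pairs, spanned_cycles))


def _peak_frequency(
    segment: np.ndarray, band: tuple[float, float], fs: float
) -> float:
    n = max(len(segment), int(0.05 * fs))
    freqs = np.fft.rfftfreq(n, 1 / fs)
    psd = np.abs(np.fft.rfft(segment, n=n)) ** 2
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        return float(band[0])
    return float(freqs[in_band][np.argmax(psd[in_band])])


def detect_hfo_channel(
    x: np.ndarray,
    sampling_rate: float,
    params: HfoDetectorParams,
    channel_id: str = "",
    start_time: float = 0.0,
) -> list[Event]:
    """Hilbert-envelope detection on one channel.

    Envelope statistics are computed on the whole segment. Returns
    events of the band's type (ripple for 80–250 Hz, fast ripple
    above) with peak_time at the envelope maximum.
    """
    if sampling_rate < 2 * params.band[1]:
        raise ValidationError("sampling rate below twice the band upper edge")
    if len(x) < sampling_rate:
        raise ValidationError("segment shorter than 1 s: not enough baseline")
    filtered = bandpass(x, params.band, sampling_rate)
    envelope = np.abs(sps.hilbert(filtered))
    if params.robust:
        center = np.median(envelope)
        spread = 1.4826 * np.median(np.abs(envelope - center))
    else:
        center = envelope.mean()
        spread = envelope.std()
    thresh = center + params.threshold_sd * spread
    boundary = center + params.boundary_sd * spread

    above = envelope > thresh
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    runs = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))

    # delimit each candidate where the envelope falls back to the
    # boundary level (the peak must cross the high threshold, but the
    # event spans its surrounding supra-boundary region)
    low = envelope > boundary
    expanded = []
    for s, e in runs:
        while s > 0 and low[s - 1]:
            s -= 1
        while e + 1 < len(low) and low[e + 1]:
            e += 1
        expanded.append((s, e))

    gap = int(params.merge_gap_ms / 1000.0 * sampling_rate)
    merged = [list(expanded[0])]
    for s, e in expanded[1:]:
        if s - merged[-1][1] <= gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    min_dur_ms = (
        params.min_duration_ms
        if params.min_duration_ms is not None
        else 1000.0 * params.min_oscillations / params.band[1]
    )
    min_len = min_dur_ms / 1000.0 * sampling_rate
    is_ripple = params.band[1] <= 250.0
    etype = EventType.RIPPLE if is_ripple else EventType.FAST_RIPPLE
    events: list[Event] = []
    for s, e in merged:
        if (e - s + 1) < min_len:
            continue
        peak_freq = _peak_frequency(filtered[s : e + 1], params.band, sampling_rate)
        # pad the window slightly for oscillation counting
        pad = int(0.005 * sampling_rate)
        s0, e0 = max(0, s - pad), min(len(x), e + 1 + pad)
        n_osc = _count_oscillations(
            filtered[s0:e0],
            float(envelope[s : e + 1].max()),
            (e - s + 1) / sampling_rate,
            peak_freq,
        )
        if n_osc < params.min_oscillations:
            continue
        peak_idx = s + int(np.argmax(envelope[s : e + 1]))
        events.append(
            Event(
                channel_id=channel_id,
                onset=start_time + s / sampling_rate,
                offset=start_time + (e + 1) / sampling_rate,
                peak_time=start_time + peak_idx / sampling_rate,
                event_type=etype,
                peak_frequency=peak_freq,
                n_oscillations=n_osc,
            )
        )
    return events


def qc_hfo(
    event: Event,
    raw: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float],
    params: QcParams | None = None,
    start_time: float = 0.0,
) -> QcStatus:
    """Automated stand-in for visual HFO review.

    Accept iff the event shows an isolated in-band spectral peak
    (island test) OR >= 4 oscillations in the filtered trace, AND is
    not explained by ringing of a sharp transient in the raw trace
    with under 4 in-band oscillations (Gibbs test).
    """
    params = params or QcParams()
    s = int((event.onset - start_time) * sampling_rate)
    e = int((event.offset - start_time) * sampling_rate)
    ctx = int(0.1 * sampling_rate)  # 100 ms context each side
    s0, e0 = max(0, s - ctx), min(len(raw), e + ctx)
    segment = raw[s:e] if e > s else raw[max(0, s - 1) : s + 1]
    context = raw[s0:e0]

    n_osc = event.n_oscillations or 0

    # island test: periodogram of the raw event segment, restricted to band
    n = max(len(segment), int(0.05 * sampling_rate))
    freqs = np.fft.rfftfreq(n, 1 / sampling_rate)
    psd = np.abs(np.fft.rfft(segment * np.hanning(len(segment)), n=n)) ** 2
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    island = False
    if in_band.sum() >= 3:
        band_psd = psd[in_band]
        k = int(np.argmax(band_psd))
        interior = 0 < k < len(band_psd) - 1
        edge = max(band_psd[0], band_psd[-1])
        island = interior and band_psd[k] > params.island_prominence_ratio * edge

    # Gibbs test: sharp transient in the raw context with few oscillations
    diffs = np.abs(np.diff(context))
    med = np.median(diffs)
    mad = 1.4826 * np.median(np.abs(diffs - med)) + 1e-12
    sharp = (diffs.max() - med) / mad > params.gibbs_z_threshold
    if sharp and n_osc < 4:
        return QcStatus.REJECTED_GIBBS
    if island or n_osc >= 4:
        return QcStatus.ACCEPTED
    return QcStatus.REJECTED_BLOB


def detect_hfos(
    recording: Recording,
    params: HfoDetectorParams,
    qc: QcParams | None = None,
    apply_qc: bool = True,
) -> list[Event]:
    """Run the Hilbert detector (and QC) on every channel; returns
    accepted events, with rejected ones kept but flagged."""
    out: list[Event] = []
    for i, ch in enumerate(recording.channel_ids):
        events = detect_hfo_channel(
            recording.signal[i],
            recording.sampling_rate,
            params,
            channel_id=ch,
            start_time=recording.start_time,
        )
        if apply_qc:
            for ev in events:
                ev.qc_status = qc_hfo(
                    ev,
                    recording.signal[i],
                    recording.sampling_rate,
                    params.band,
                    qc,
                    start_time=recording.start_time,
                )
        out.extend(events)
    return out


def accepted(events: list[Event]) -> list[Event]:
    return [ev for ev in events if ev.qc_status is QcStatus.ACCEPTED]


# ---------------------------------------------------------------------------
# stand-in spike detector
# ---------------------------------------------------------------------------

def detect_spikes_standin(
    recording: Recording, params: SpikeDetectorParams | None = None
) -> list[Event]:
    """Envelope z-score spike detector in a sharp-activity sub-band.

    Expects a recording already passed through
    :func:`preprocess_for_spikes`. The statistic is the Hilbert
    envelope of the 10–60 Hz band-passed trace — the band where spike
    transients concentrate their energy while the 1/f background is
    already weak — z-scored against channel-wise robust (median/MAD)
    statistics. Supra-threshold samples seed events, merged within the
    refractory period and bounded to 20–200 ms.
    """
    params = params or SpikeDetectorParams()
    fs = recording.sampling_rate
    refractory = int(params.refractory_ms / 1000.0 * fs)
    min_half = int(params.min_duration_ms / 2000.0 * fs)
    max_half = int(params.max_duration_ms / 2000.0 * fs)
    events: list[Event] = []
    for i, ch in enumerate(recording.channel_ids):
        x = recording.signal[i]
        env = np.abs(sps.hilbert(bandpass(x, params.sharp_band, fs)))
        med = np.median(env)
        mad = 1.4826 * np.median(np.abs(env - med)) + 1e-12
        z = (env - med) / mad
        hot = np.flatnonzero(z > params.z_threshold)
        if len(hot) == 0:
            continue
        groups = np.split(hot, np.flatnonzero(np.diff(hot) > refractory) + 1)
        for g in groups:
            peak = g[np.argmax(z[g])]
            half = int(np.clip(g[-1] - g[0], 2 * min_half, 2 * max_half) / 2)
            half = max(half, min_half)
            onset = max(0, peak - half)
            offset = min(len(x), peak + half + 1)
            events.append(
                Event(
                    channel_id=ch,
                    onset=recording.start_time + onset / fs,
                    offset=recording.start_time + offset / fs,
                    peak_time=recording.start_time + peak / fs,
                    event_type=EventType.SPIKE,
                )
            )
    return events


# ---------------------------------------------------------------------------
# scoring against reference annotations
# ---------------------------------------------------------------------------

def match_events(
    detected: list[Event],
    reference: list[Event],
    tolerance_ms: float,
) -> tuple[float, float, list[tuple[Event, Event]]]:
    """Greedy one-to-one nearest-peak matching per channel.

    Returns (sensitivity, precision, matched pairs): sensitivity =
    matches / |reference|, precision = matches / |detected|.
    """
    if tolerance_ms < 0:
        raise ValidationError("tolerance must be nonnegative")
    tol = tolerance_ms / 1000.0
    pairs: list[tuple[Event, Event]] = []
    channels = {ev.channel_id for ev in detected} | {ev.channel_id for ev in reference}
    for ch in sorted(channels):
        det = sorted(
            (ev for ev in detected if ev.channel_id == ch), key=lambda e: e.peak_time
        )
        ref = sorted(
            (ev for ev in reference if ev.channel_id == ch), key=lambda e: e.peak_time
        )
        candidates = [
            (abs(d.peak_time - r.peak_time), di, ri)
            for di, d in enumerate(det)
            for ri, r in enumerate(ref)
            if abs(d.peak_time - r.peak_time) <= tol
        ]
        candidates.sort(key=lambda c: c[0])
        used_d: set[int] = set()
        used_r: set[int] = set()
        for _, di, ri in candidates:
            if di in used_d or ri in used_r:
                continue
            used_d.add(di)
            used_r.add(ri)
            pairs.append((det[di], ref[ri]))
    sensitivity = len(pairs) / len(reference) if reference else float("nan")
    precision = len(pairs) / len(detected) if detected else float("nan")
    return sensitivity, precision, pairs
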