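"""Synthetic interictal iEEG: background, event waveforms, patients, cohorts.

The generator emulates the statistical structure the downstream
analysis assumes: 1/f background, brief spike transients and
band-limited ripple / fast-ripple bursts arriving as Poisson
processes, co-occurrence planned within a +/-50 ms window, biomarker
rates doubled on the epileptogenic channel set, and an outcome model
in which good surgical outcome corresponds to a resection ratio of the
rule biomarker above a cut-off (0.5 by default).

Co-occurrence is planned at generation time: each planned cluster has
an exact category, so the temporal classifier can be tested against
exact ground truth. Planned cluster anchors on a channel are spaced at
least 300 ms apart, which guarantees (jitter <= 50 ms) that single-
linkage clustering recovers the planned clusters exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cooccur import build_clusters, categorize_events, compute_rates
from .types import (
    BiomarkerRates,
    ChannelInfo,
    ElectrodeKind,
    Event,
    EventType,
    Lobe,
    PatientRecord,
    Recording,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: minimum spacing between planned cluster anchors on one channel (s)
ANCHOR_SEPARATION = 0.3
#: events are never planned closer than this to the segment edges (s)
EDGE_MARGIN = 0.1


class GenerationError(RuntimeError):
    """Raised when the requested synthetic structure is infeasible."""


@dataclass
class SynthParams:
    """Parameters of one synthetic patient.

    Rates are baseline events/min outside the epileptogenic set;
    channels inside it receive ``rate * inside_multiplier`` and a
    spike-ripple co-occurrence probability boosted by
    ``cooccur_boost`` (the concentration of spike-on-ripple events in
    epileptogenic tissue that drives the outcome model).
    """

    n_channels: int = 32
    duration: float = 600.0  # seconds
    sampling_rate: float = 2000.0
    background_exponent: float = 1.0  # 1/f^alpha
    background_rms: float = 25.0  # microvolts
    spike_rate: float = 1.3  # events/min, baseline
    ripple_rate: float = 0.9
    fr_rate: float = 0.1
    inside_multiplier: float = 2.0
    p_cooccur: dict = field(
        default_factory=lambda: {
            "r_given_s": 0.11,
            "fr_given_s": 0.02,
            "fr_given_r": 0.05,
        }
    )
    cooccur_boost: float = 4.0  # applied to r_given_s on epileptogenic channels
    cooccur_jitter: float = 0.05  # seconds, uniform in [-jitter, +jitter]
    snr: float = 5.0  # event amplitude / in-band background RMS
    n_soz_channels: int = 4
    n_resected_channels: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.spike_rate, self.ripple_rate, self.fr_rate) < 0:
            raise ValidationError("rates must be nonnegative")
        for k, p in self.p_cooccur.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"p_cooccur[{k}] out of [0, 1]")
        if self.fr_rate > 0 and self.sampling_rate < 1000.0:
            raise ValidationError(
                "fast ripples (up to 500 Hz) need sampling_rate >= 1000 Hz"
            )
        if self.cooccur_jitter > 0.05:
            raise ValidationError("cooccur_jitter must be <= 50 ms")
        if self.n_soz_channels > self.n_channels:
            raise ValidationError("more SOZ channels than channels")
        if self.n_resected_channels > self.n_channels:
            raise ValidationError("more resected channels than channels")


@dataclass
class CohortParams:
    """Cohort-level design: sizes, outcome rule, label noise."""

    n_patients: int = 40
    n_good: int = 26
    outcome_rule_biomarker: str | None = "S+R"
    outcome_threshold: float = 0.5
    label_noise: float = 0.1
    patient_params: SynthParams = field(default_factory=SynthParams)
    duration_range: tuple[float, float] = (600.0, 600.0)  # seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_good > self.n_patients:
            raise ValidationError("n_good cannot exceed n_patients")
        if not 0 <= self.label_noise <= 0.5:
            raise ValidationError("label_noise must be in [0, 0.5]")


# ---------------------------------------------------------------------------
# background and waveforms
# ---------------------------------------------------------------------------

def synth_background(
    params: SynthParams, seed: int | None = None
) -> Recording:
    """Independent 1/f^alpha noise per channel at the target RMS."""
    if params.background_exponent < 0:
        raise ValidationError("background exponent must be >= 0")
    if params.duration <= 0 or params.sampling_rate <= 0:
        raise ValidationError("duration and sampling_rate must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(params.duration * params.sampling_rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / params.sampling_rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-params.background_exponent / 2.0)
    shape[0] = 0.0  # no DC
    sig = np.empty((params.n_channels, n))
    for ch in range(params.n_channels):
        spec = np.fft.rfft(rng.standard_normal(n)) * shape
        x = np.fft.irfft(spec, n=n)
        rms = np.sqrt(np.mean(x**2))
        sig[ch] = x * (params.background_rms / rms) if rms > 0 else x
    return Recording(
        signal=sig,
        sampling_rate=params.sampling_rate,
        channel_ids=[f"CH{i:03d}" for i in range(params.n_channels)],
    )


def synth_event_waveform(
    event_type: EventType | str,
    f0: float | None,
    n_cycles: int | None,
    amplitude: float,
    sampling_rate: float,
) -> np.ndarray:
    """Canonical event shapes used for injection.

    Ripple / fast ripple: Hann-windowed cosine of ``n_cycles / f0``
    seconds, so the spectral content is an isolated in-band peak.
    Spike: biphasic sharp transient of ~60 ms built from two opposed
    Gaussian lobes, dominant energy below 70 Hz. Peak absolute
    amplitude is normalized to ``amplitude``.
    """
    event_type = EventType(event_type)
    if event_type in (EventType.RIPPLE, EventType.FAST_RIPPLE):
        if f0 is None or n_cycles is None:
            raise ValidationError("HFO waveform needs f0 and n_cycles")
        if f0 >= sampling_rate / 2:
            raise ValidationError(
                f"f0 {f0} Hz at or above Nyquist ({sampling_rate / 2} Hz)"
            )
        if n_cycles < 1:
            raise ValidationError("n_cycles must be >= 1")
        lo, hi = (80.0, 250.0) if event_type is EventType.RIPPLE else (250.0, 500.0)
        if not (lo <= f0 <= hi) and not (
            event_type is EventType.FAST_RIPPLE and lo < f0 <= hi
        ):
            raise ValidationError(f"{event_type.value} f0 {f0} Hz outside band")
        dur = n_cycles / f0
        n = max(3, int(round(dur * sampling_rate)))
        t = np.arange(n) / sampling_rate
        w = np.hanning(n) * np.cos(2 * np.pi * f0 * (t - t[n // 2]))
    else:  # spike
        dur = 0.06
        n = int(round(dur * sampling_rate))
        t = np.arange(n) / sampling_rate
        t1, s1 = 0.022, 0.006  # sharp lobe
        t2, s2 = 0.042, 0.012  # opposing slow lobe
        w = np.exp(-(((t - t1) / s1) ** 2)) - 0.55 * np.exp(-(((t - t2) / s2) ** 2))
    peak = np.max(np.abs(w))
    if peak == 0:
        raise ValidationError("degenerate waveform")
    return w * (amplitude / peak)


# ---------------------------------------------------------------------------
# planning
# ---------------------------------------------------------------------------

def make_channels(params: SynthParams) -> list[ChannelInfo]:
    """Default geometry: SOZ = first n_soz channels, contained in the
    resected set (first n_resected channels)."""
    lobes = list(Lobe)
    out = []
    for i in range(params.n_channels):
        out.append(
            ChannelInfo(
                channel_id=f"CH{i:03d}",
                lobe=lobes[i % 4],
                is_soz=i < params.n_soz_channels,
                is_resected=i < params.n_resected_channels,
                electrode_kind=ElectrodeKind.DEPTH if i % 2 else ElectrodeKind.GRID,
            )
        )
    return out


def _draw_anchors(rng, n: int, duration: float) -> np.ndarray:
    """n anchor times in [margin, duration - margin], pairwise >= 300 ms apart.

    Uniform under the spacing constraint (draw in the shrunk interval,
    sort, fan out). Thins with a warning when the request cannot fit.
    """
    usable = duration - 2 * EDGE_MARGIN
    max_n = int(usable / ANCHOR_SEPARATION)
    if n > max_n:
        logger.warning(
            "thinning planned events: %d requested, %d fit in %.1f s", n, max_n, duration
        )
        n = max_n
    if n <= 0:
        return np.empty(0)
    slack = usable - (n - 1) * ANCHOR_SEPARATION
    pts = np.sort(rng.uniform(0.0, slack, size=n))
    return EDGE_MARGIN + pts + ANCHOR_SEPARATION * np.arange(n)


@dataclass
class PlannedCluster:
    channel_id: str
    anchor: float
    category: str
    events: list[Event]


def _hfo_event(
    rng, channel_id: str, peak: float, etype: EventType
) -> tuple[Event, float, int]:
    if etype is EventType.RIPPLE:
        f0 = rng.uniform(100.0, 200.0)
    else:
        f0 = rng.uniform(270.0, 420.0)
    n_cycles = 8
    half = 0.5 * n_cycles / f0
    return (
        Event(
            channel_id=channel_id,
            onset=peak - half,
            offset=peak + half,
            peak_time=peak,
            event_type=etype,
            peak_frequency=f0,
            n_oscillations=n_cycles,
        ),
        f0,
        n_cycles,
    )


def plan_patient_events(
    params: SynthParams, seed: int | None = None
) -> tuple[list[Event], list[PlannedCluster], list[ChannelInfo]]:
    """Draw the planned clusters and their member events for one patient.

    Returns (events, planned clusters, channels). Epileptogenic
    channels (the resected set) receive rate * inside_multiplier and a
    boosted spike-ripple co-occurrence probability.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    channels = make_channels(params)
    minutes = params.duration / 60.0
    p = params.p_cooccur
    events: list[Event] = []
    planned: list[PlannedCluster] = []

    for ch in channels:
        inside = ch.is_resected
        mult = params.inside_multiplier if inside else 1.0
        p_rs = min(1.0, p.get("r_given_s", 0.0) * (params.cooccur_boost if inside else 1.0))
        p_fs = p.get("fr_given_s", 0.0)
        p_fr = p.get("fr_given_r", 0.0)

        n_s = rng.poisson(params.spike_rate * mult * minutes)
        n_r = rng.poisson(params.ripple_rate * mult * minutes)
        n_f = rng.poisson(params.fr_rate * mult * minutes)
        anchors = _draw_anchors(rng, n_s + n_r + n_f, params.duration)
        kinds = np.array(["S"] * n_s + ["R"] * n_r + ["F"] * n_f)[: len(anchors)]
        rng.shuffle(kinds)

        for t0, kind in zip(anchors, kinds):
            members: list[Event] = []
            if kind == "S":
                members.append(
                    Event(
                        channel_id=ch.channel_id,
                        onset=t0 - 0.03,
                        offset=t0 + 0.03,
                        peak_time=t0,
                        event_type=EventType.SPIKE,
                    )
                )
                if rng.random() < p_rs:
                    peak = t0 + rng.uniform(-params.cooccur_jitter, params.cooccur_jitter)
                    members.append(_hfo_event(rng, ch.channel_id, peak, EventType.RIPPLE)[0])
                if rng.random() < p_fs:
                    peak = t0 + rng.uniform(-params.cooccur_jitter, params.cooccur_jitter)
                    members.append(
                        _hfo_event(rng, ch.channel_id, peak, EventType.FAST_RIPPLE)[0]
                    )
            elif kind == "R":
                members.append(_hfo_event(rng, ch.channel_id, t0, EventType.RIPPLE)[0])
                if rng.random() < p_fr:
                    peak = t0 + rng.uniform(-params.cooccur_jitter, params.cooccur_jitter)
                    members.append(
                        _hfo_event(rng, ch.channel_id, peak, EventType.FAST_RIPPLE)[0]
                    )
            else:
                members.append(
                    _hfo_event(rng, ch.channel_id, t0, EventType.FAST_RIPPLE)[0]
                )
            cluster = PlannedCluster(
                channel_id=ch.channel_id,
                anchor=t0,
                category=_category_of(members),
                events=members,
            )
            planned.append(cluster)
            events.extend(members)
    return events, planned, channels


def _category_of(members: list[Event]) -> str:
    ts = {ev.event_type.short for ev in members}
    parts = [t for t in ("S", "R", "FR") if t in ts]
    return f"{parts[0]}_only" if len(parts) == 1 else "+".join(parts)


def planned_counts(
    planned: list[PlannedCluster], channel_ids: list[str]
) -> dict[str, dict[str, int]]:
    """Per-channel category counts implied by the plan (no clustering)."""
    from .types import CATEGORIES

    counts = {ch: {cat: 0 for cat in CATEGORIES} for ch in channel_ids}
    for cl in planned:
        row = counts[cl.channel_id]
        cat = cl.category
        row[cat] += 1
        for ev in cl.events:
            row[f"All_{ev.event_type.short}"] += 1
        if cat in ("S+R", "S+FR", "S+R+FR"):
            row["S+HFO"] += 1
    return counts


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _band_amplitude(x: np.ndarray, band: tuple[float, float], fs: float) -> float:
    """Background amplitude in a band: mean analytic-signal envelope of
    the band-passed trace (the detector's own amplitude scale)."""
    from scipy.signal import hilbert

    from .detect import bandpass

    return float(np.mean(np.abs(hilbert(bandpass(x, band, fs)))))


def synth_patient(
    params: SynthParams, seed: int | None = None
) -> tuple[Recording, list[Event], list[ChannelInfo]]:
    """Full synthetic patient: background + injected events + labels.

    Event peak amplitudes are ``snr`` times the realized background
    amplitude (mean analytic envelope) in the event's own band
    (1–70 Hz for spikes, 80–250 / 250–500 Hz for ripples / fast
    ripples), measured per channel.
    """
    base_seed = params.seed if seed is None else seed
    rec = synth_background(params, seed=base_seed)
    events, planned, channels = plan_patient_events(params, seed=base_seed + 1)
    rng = np.random.default_rng(base_seed + 2)
    fs = params.sampling_rate
    bands = {
        EventType.SPIKE: (1.0, 70.0),
        EventType.RIPPLE: (80.0, 250.0),
        EventType.FAST_RIPPLE: (250.0, min(500.0, fs / 2 * 0.95)),
    }
    idx = {c: i for i, c in enumerate(rec.channel_ids)}
    # realized in-band background RMS per channel per band
    rms_cache: dict[tuple[int, EventType], float] = {}
    for ev in events:
        ci = idx[ev.channel_id]
        key = (ci, ev.event_type)
        if key not in rms_cache:
            rms_cache[key] = _band_amplitude(rec.signal[ci], bands[ev.event_type], fs)
        amp = params.snr * rms_cache[key]
        if ev.event_type is EventType.SPIKE:
            w = synth_event_waveform(ev.event_type, None, None, amp, fs)
        else:
            w = synth_event_waveform(
                ev.event_type, ev.peak_frequency, ev.n_oscillations, amp, fs
            )
        center = int(round(ev.peak_time * fs))
        start = center - len(w) // 2
        lo = max(0, start)
        hi = min(rec.n_samples, start + len(w))
        if hi > lo:
            rec.signal[ci, lo:hi] += w[lo - start : hi - start]
    _ = rng  # reserved for future amplitude jitter
    return rec, events, channels


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _truth_rates(
    planned: list[PlannedCluster], channels: list[ChannelInfo], minutes: float
) -> BiomarkerRates:
    counts = planned_counts(planned, [c.channel_id for c in channels])
    return compute_rates(counts, minutes, [c.channel_id for c in channels])


def _poor_geometry(channels: list[ChannelInfo], params: SynthParams) -> list[ChannelInfo]:
    """Resect only a minority of the epileptogenic set, making up the
    count with unremarkable channels (poor-outcome geometry)."""
    n_e = params.n_resected_channels
    keep = max(1, n_e // 3)
    out = []
    for i, ch in enumerate(channels):
        resected = i < keep or (n_e <= i < n_e + (n_e - keep))
        out.append(replace(ch, is_resected=resected))
    return out


def synth_cohort(
    params: CohortParams,
) -> tuple[list[PatientRecord], dict[str, list[Event]]]:
    """Generate the cohort at the event level (no waveform synthesis).

    Designed-good patients resect the whole epileptogenic set, so the
    ground-truth resection ratio of the rule biomarker exceeds the
    threshold; designed-poor patients resect only part of it. Outcome
    labels are then flipped independently with ``label_noise``. When
    ``outcome_rule_biomarker`` is None, no geometric constraint is
    imposed and labels are assigned by design alone (null model).
    """
    rng = np.random.default_rng(params.seed)
    records: list[PatientRecord] = []
    truths: dict[str, list[Event]] = {}
    from .outcome import resection_ratio

    for i in range(params.n_patients):
        designed_good = i < params.n_good
        duration = rng.uniform(*params.duration_range)
        pp = replace(
            params.patient_params,
            duration=duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        minutes = duration / 60.0
        for attempt in range(20):
            events, planned, channels = plan_patient_events(pp, seed=pp.seed + attempt)
            if params.outcome_rule_biomarker is None:
                break
            if not designed_good:
                channels = _poor_geometry(channels, pp)
            rates = _truth_rates(planned, channels, minutes)
            ratio = resection_ratio(rates, channels, params.outcome_rule_biomarker)
            if ratio is None:
                continue
            if designed_good and ratio > params.outcome_threshold:
                break
            if not designed_good and ratio < params.outcome_threshold:
                break
        else:
            raise GenerationError(
                f"patient {i}: could not satisfy resection-ratio design "
                f"(rule {params.outcome_rule_biomarker} vs {params.outcome_threshold})"
            )
        if params.outcome_rule_biomarker is None:
            rates = _truth_rates(planned, channels, minutes)
        outcome_good = designed_good
        if rng.random() < params.label_noise:
            outcome_good = not outcome_good
        pid = f"P{i + 1:03d}"
        records.append(
            PatientRecord(
                patient_id=pid,
                rates=rates,
                channels=channels,
                engel="1a" if outcome_good else "3",
                follow_up=float(rng.uniform(1.0, 8.0)),
            )
        )
        truths[pid] = events
    return records, truths


def recovered_rates(
    events: list[Event], channels: list[ChannelInfo], minutes: float
) -> BiomarkerRates:
    """Rates obtained by actually clustering the events (cross-check
    against the planned counts)."""
    clusters = build_clusters(events)
    counts = categorize_events(clusters, events)
    return compute_rates(counts, minutes, [c.channel_id for c in channels])
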