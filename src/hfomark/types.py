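"""Domain types shared by every stage of the biomarker pipeline.

The vocabulary follows clinical iEEG practice: a *recording* is a
channels-by-samples matrix in microvolts; *events* are transient
detections (interictal spikes, ripples 80–250 Hz, fast ripples
250–500 Hz); *clusters* group same-channel events whose peaks fall
within a co-occurrence window of each other; per-channel *rates* in
events/min feed the localization and outcome analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

# The 11 biomarker categories. All_* count raw events of one type;
# the combination categories count clusters by their exact type set;
# S+HFO counts clusters containing a spike and at least one HFO.
CATEGORIES = (
    "All_S",
    "All_R",
    "All_FR",
    "S_only",
    "R_only",
    "FR_only",
    "S+R",
    "S+FR",
    "R+FR",
    "S+R+FR",
    "S+HFO",
)

CLUSTER_CATEGORIES = ("S_only", "R_only", "FR_only", "S+R", "S+FR", "R+FR", "S+R+FR")

RIPPLE_BAND = (80.0, 250.0)
FAST_RIPPLE_BAND = (250.0, 500.0)


class EventType(str, enum.Enum):
    SPIKE = "spike"
    RIPPLE = "ripple"
    FAST_RIPPLE = "fast_ripple"

    @property
    def short(self) -> str:
        return _SHORT[self.value]


_SHORT = {"spike": "S", "ripple": "R", "fast_ripple": "FR"}


class Lobe(str, enum.Enum):
    TEMPORAL = "temporal"
    FRONTAL = "frontal"
    PARIETAL = "parietal"
    OCCIPITAL = "occipital"
    OTHER = "other"


class ElectrodeKind(str, enum.Enum):
    GRID = "grid"
    STRIP = "strip"
    DEPTH = "depth"


class QcStatus(str, enum.Enum):
    ACCEPTED = "accepted"
    REJECTED_BLOB = "rejected_blob"
    REJECTED_GIBBS = "rejected_gibbs"
    REJECTED_SHORT = "rejected_short"


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class FormatError(ValidationError):
    """Unreadable or structurally invalid file."""


class UnsupportedLayoutError(ValidationError):
    """Valid file, but a layout the pipeline does not handle."""


@dataclass
class Recording:
    """Multichannel iEEG segment.

    signal : (n_channels, n_samples) float array, microvolts
    sampling_rate : Hz
    channel_ids : unique names, one per signal row
    start_time : offset of sample 0 in seconds (origin of event times)
    """

    signal: np.ndarray
    sampling_rate: float
    channel_ids: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValidationError("signal contains non-finite samples")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise ValidationError("channel_ids length must match signal rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("channel_ids must be unique")
        if self.signal.shape[1] == 0:
            raise ValidationError("recording has zero duration")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, channel_id: str) -> np.ndarray:
        return self.signal[self.channel_ids.index(channel_id)]


@dataclass
class ChannelInfo:
    """Per-contact metadata: anatomical lobe, SOZ and resection flags."""

    channel_id: str
    lobe: Lobe = Lobe.OTHER
    is_soz: bool = False
    is_resected: bool = False
    electrode_kind: ElectrodeKind = ElectrodeKind.GRID


@dataclass
class Event:
    """A detected transient on one channel.

    Times are seconds from recording start; intervals are half-open
    [onset, offset). peak_frequency / n_oscillations are meaningful
    for HFOs only.
    """

    channel_id: str
    onset: float
    offset: float
    event_type: EventType
    peak_time: float | None = None
    peak_frequency: float | None = None
    n_oscillations: int | None = None
    qc_status: QcStatus = QcStatus.ACCEPTED

    def __post_init__(self) -> None:
        if isinstance(self.event_type, str):
            self.event_type = EventType(self.event_type)
        if self.peak_time is None:
            self.peak_time = 0.5 * (self.onset + self.offset)
        if self.onset > self.offset:
            raise ValidationError(
                f"event onset {self.onset} > offset {self.offset}"
            )
        if not (self.onset <= self.peak_time <= self.offset):
            raise ValidationError("peak_time must lie within [onset, offset]")


@dataclass
class EventCluster:
    """Same-channel events chained by peak-time proximity (single linkage)."""

    channel_id: str
    members: list[Event]

    @property
    def type_set(self) -> frozenset[str]:
        return frozenset(ev.event_type.short for ev in self.members)

    @property
    def category(self) -> str:
        ts = self.type_set
        parts = [t for t in ("S", "R", "FR") if t in ts]
        if len(parts) == 1:
            return f"{parts[0]}_only"
        return "+".join(parts)


@dataclass
class BiomarkerRates:
    """Per-channel, per-category occurrence rates in events/min.

    ``table[channel_id][category]`` -> events/min. Counts are
    recoverable as rate * duration.
    """

    table: dict[str, dict[str, float]]
    recording_duration: float  # minutes

    def __post_init__(self) -> None:
        if self.recording_duration <= 0:
            raise ValidationError("recording_duration must be positive minutes")
        for ch, row in self.table.items():
            for cat, v in row.items():
                if v < 0:
                    raise ValidationError(f"negative rate for {ch}/{cat}")

    def rate(self, channel_id: str, category: str) -> float:
        return self.table[channel_id].get(category, 0.0)

    def channel_ids(self) -> list[str]:
        return list(self.table.keys())

    def category_vector(self, category: str, channel_ids=None) -> np.ndarray:
        ids = channel_ids if channel_ids is not None else self.channel_ids()
        return np.array([self.rate(c, category) for c in ids], dtype=float)


def parse_engel(label: str) -> tuple[str, str]:
    """Normalize an Engel class label -> (class string, 'good'|'poor').

    Any class beginning with 1/I (IA–ID) is good; II and above is poor.
    Case-insensitive; accepts arabic ('1a', '3') and roman ('IA', 'III')
    forms.
    """
    s = str(label).strip().lower()
    if not s:
        raise ValidationError("empty Engel label")
    roman = {"iv": "4", "iii": "3", "ii": "2", "i": "1"}
    for rom, arab in roman.items():
        if s.startswith(rom):
            s = arab + s[len(rom):]
            break
    if s[0] not in "1234":
        raise ValidationError(f"unrecognized Engel class: {label!r}")
    outcome = "good" if s[0] == "1" else "poor"
    return s, outcome


@dataclass
class PatientRecord:
    """One cohort unit: rates + channel labels + surgical outcome."""

    patient_id: str
    rates: BiomarkerRates
    channels: list[ChannelInfo]
    engel: str
    follow_up: float = 1.0
    outcome: str = field(default="")

    def __post_init__(self) -> None:
        cls, derived = parse_engel(self.engel)
        self.engel = cls
        if not self.outcome:
            self.outcome = derived
        elif self.outcome not in ("good", "poor"):
            raise ValidationError("outcome must be 'good' or 'poor'")

    @property
    def good_outcome(self) -> bool:
        return self.outcome == "good"


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else float("nan")


@dataclass
class OutcomeMetrics:
    """Youden-point classification metric suite.

    markedness = PPV + NPV - 1; youden_j = sensitivity + specificity - 1.
    """

    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    markedness: float
    fpr: float
    accuracy: float
    youden_j: float
    threshold: float
    confusion: ConfusionMatrix | None = None
    n_excluded: int = 0

    @classmethod
    def from_confusion(
        cls, cm: ConfusionMatrix, auc: float, threshold: float, n_excluded: int = 0
    ) -> "OutcomeMetrics":
        sens = _safe_div(cm.tp, cm.tp + cm.fn)
        spec = _safe_div(cm.tn, cm.tn + cm.fp)
        ppv = _safe_div(cm.tp, cm.tp + cm.fp)
        npv = _safe_div(cm.tn, cm.tn + cm.fn)
        return cls(
            auc=auc,
            sensitivity=sens,
            specificity=spec,
            ppv=ppv,
            npv=npv,
            markedness=ppv + npv - 1.0,
            fpr=1.0 - spec,
            accuracy=_safe_div(cm.tp + cm.tn, cm.total),
            youden_j=sens + spec - 1.0,
            threshold=threshold,
            confusion=cm,
            n_excluded=n_excluded,
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "markedness": self.markedness,
            "fpr": self.fpr,
            "accuracy": self.accuracy,
            "youden_j": self.youden_j,
            "threshold": self.threshold,
        }


@dataclass
class LocalizationScore:
    """Restricted-specificity pAUC (specificity 85–100%) and sens@spec.

    pauc_norm = pauc_raw / 0.15, the maximum attainable restricted area.
    """

    pauc_raw: float
    pauc_norm: float
    sens_at_spec: dict[float, float]

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.pauc_raw <= 0.15 + 1e-12):
            raise ValidationError("pauc_raw out of [0, 0.15]")
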