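import numpy as np
import pytest

from hfomark.synth import CohortParams, SynthParams, synth_cohort
from hfomark.types import Event, EventType


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic cohort: 40 patients, 26 good, S+R rule at
    0.5, 10% label noise."""
    return synth_cohort(CohortParams(seed=42))


@pytest.fixture(scope="session")
def detection_patient_params():
    """Patient geometry used for detector-recovery checks: modest channel
    count, 60 s, SNR 5, flat rates (no inside elevation)."""
    def make(seed):
        return SynthParams(
            n_channels=8,
            duration=60.0,
            seed=seed,
            spike_rate=2.0,
            ripple_rate=3.0,
            fr_rate=2.0,
            snr=5.0,
            n_soz_channels=2,
            n_resected_channels=2,
            inside_multiplier=1.0,
        )
    return make


def random_events(rng, n, n_channels=3, t_max=10.0, window_scale=0.05):
    """Random mixed-type events for clustering stress tests."""
    types = [EventType.SPIKE, EventType.RIPPLE, EventType.FAST_RIPPLE]
    events = []
    for _ in range(n):
        peak = rng.uniform(0, t_max)
        half = rng.uniform(0.005, 0.03)
        events.append(
            Event(
                channel_id=f"C{rng.integers(n_channels)}",
                onset=peak - half,
                offset=peak + half,
                peak_time=peak,
                event_type=types[rng.integers(3)],
            )
        )
    return events
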