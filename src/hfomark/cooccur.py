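"""Temporal categorization of spikes, ripples and fast ripples.

Events on the same channel whose peak times fall within a +/-50 ms
window are considered co-occurring; chains of pairwise-close events
merge into one cluster (single linkage / connected components). Each
cluster's distinct type set assigns it to one of the combination
categories (S_only ... S+R+FR); the All_S / All_R / All_FR tallies
count raw events of each type, and S+HFO counts clusters containing a
spike together with at least one HFO.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd

from .types import (
    BiomarkerRates,
    CATEGORIES,
    CLUSTER_CATEGORIES,
    ChannelInfo,
    Event,
    EventCluster,
    ValidationError,
)

DEFAULT_WINDOW_MS = 50.0


def build_clusters(
    events: list[Event], window_ms: float = DEFAULT_WINDOW_MS
) -> list[EventCluster]:
    """Group same-channel events whose peak times chain within the window.

    The window is closed: a peak-time gap of exactly ``window_ms``
    counts as co-occurring. Events on different channels never share a
    cluster.
    """
    if window_ms < 0:
        raise ValidationError("window must be nonnegative")
    window = window_ms / 1000.0
    by_channel: dict[str, list[Event]] = defaultdict(list)
    for ev in events:
        by_channel[ev.channel_id].append(ev)

    clusters: list[EventCluster] = []
    for channel_id in sorted(by_channel):
        chan_events = sorted(by_channel[channel_id], key=lambda e: e.peak_time)
        current: list[Event] = []
        for ev in chan_events:
            # sorted peaks: single-linkage components are runs of
            # consecutive gaps <= window
            if current and ev.peak_time - current[-1].peak_time > window + 1e-12:
                clusters.append(EventCluster(channel_id, current))
                current = []
            current.append(ev)
        if current:
            clusters.append(EventCluster(channel_id, current))
    return clusters


def categorize_events(
    clusters: list[EventCluster], events: list[Event]
) -> dict[str, dict[str, int]]:
    """Per-channel counts for all 11 categories.

    Returns ``{channel_id: {category: count}}``. Combination categories
    count clusters (one S+R per cluster, however many constituent
    events); All_* count individual events.
    """
    channels = sorted(
        {ev.channel_id for ev in events} | {cl.channel_id for cl in clusters}
    )
    counts = {ch: {cat: 0 for cat in CATEGORIES} for ch in channels}

    for ev in events:
        counts[ev.channel_id][f"All_{ev.event_type.short}"] += 1
    for cl in clusters:
        counts[cl.channel_id][cl.category] += 1
        ts = cl.type_set
        if "S" in ts and ({"R", "FR"} & ts):
            counts[cl.channel_id]["S+HFO"] += 1
    return counts


def per_event_labels(clusters: list[EventCluster]) -> pd.DataFrame:
    """One row per event with its cluster category and companion flags.

    A spike is "on a ripple" iff its cluster also contains a ripple;
    likewise for the other type pairs. Used for proportion reporting.
    """
    rows = []
    for i, cl in enumerate(clusters):
        ts = cl.type_set
        for ev in cl.members:
            rows.append(
                {
                    "channel_id": ev.channel_id,
                    "peak_time": ev.peak_time,
                    "event_type": ev.event_type.value,
                    "cluster_index": i,
                    "cluster_category": cl.category,
                    "with_spike": "S" in ts,
                    "with_ripple": "R" in ts,
                    "with_fast_ripple": "FR" in ts,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "channel_id",
            "peak_time",
            "event_type",
            "cluster_index",
            "cluster_category",
            "with_spike",
            "with_ripple",
            "with_fast_ripple",
        ],
    )


def compute_rates(
    counts: dict[str, dict[str, int]],
    duration_min: float,
    channel_ids: list[str] | None = None,
) -> BiomarkerRates:
    """Counts -> events/min. Channels without events get all-zero rows."""
    if duration_min <= 0:
        raise ValidationError("recording duration must be positive")
    ids = channel_ids if channel_ids is not None else sorted(counts)
    table = {
        ch: {
            cat: counts.get(ch, {}).get(cat, 0) / duration_min for cat in CATEGORIES
        }
        for ch in ids
    }
    return BiomarkerRates(table=table, recording_duration=duration_min)


def events_to_rates(
    events: list[Event],
    duration_min: float,
    channel_ids: list[str] | None = None,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> BiomarkerRates:
    """Convenience: cluster, categorize and convert to rates in one step."""
    clusters = build_clusters(events, window_ms)
    counts = categorize_events(clusters, events)
    return compute_rates(counts, duration_min, channel_ids)


def area_percentage(
    channels: list[ChannelInfo],
    rates: BiomarkerRates | None = None,
    category: str | None = None,
) -> dict[str, float]:
    """Percentage of implanted channels in each area.

    Always reports the SOZ and resected-area percentages; when a rates
    table and category are given, also the percentage of channels with
    a nonzero rate for that biomarker.
    """
    if not channels:
        raise ValidationError("need at least one channel")
    n = len(channels)
    out = {
        "soz_pct": 100.0 * sum(c.is_soz for c in channels) / n,
        "resected_pct": 100.0 * sum(c.is_resected for c in channels) / n,
    }
    if rates is not None and category is not None:
        active = sum(
            1 for c in channels if rates.rate(c.channel_id, category) > 0
        )
        out["biomarker_pct"] = 100.0 * active / n
    return out


def rates_to_frame(rates: BiomarkerRates) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rates.table, orient="index")[list(CATEGORIES)]
    df.index.name = "channel_id"
    return df


def frame_to_rates(df: pd.DataFrame, duration_min: float) -> BiomarkerRates:
    table = {
        str(idx): {cat: float(row[cat]) for cat in CATEGORIES if cat in row}
        for idx, row in df.iterrows()
    }
    return BiomarkerRates(table=table, recording_duration=duration_min)


def check_category_identities(counts: dict[str, dict[str, int]]) -> None:
    """Raise AssertionError if the category algebra is violated.

    Cluster-level identity: clusters containing a spike =
    S_only + S+R + S+FR + S+R+FR, and S+HFO = S+R + S+FR + S+R+FR.
    """
    for ch, row in counts.items():
        s_clusters = row["S_only"] + row["S+R"] + row["S+FR"] + row["S+R+FR"]
        assert row["S+HFO"] == row["S+R"] + row["S+FR"] + row["S+R+FR"], ch
        assert s_clusters >= 0
        for cat in CLUSTER_CATEGORIES:
            assert row[cat] >= 0, ch
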