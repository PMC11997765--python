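"""Surgical-outcome prediction from the resection ratio.

The resection ratio of a biomarker is the fraction of its total rate
carried by resected contacts: 1 means every generator of the
biomarker was removed, 0 means none. Patients without any event of a
biomarker have an undefined ratio and are excluded from that
biomarker's analysis (the exclusion count is reported). The SOZ ratio
is the fraction of SOZ contacts that were resected.

Outcome (good = Engel I) is predicted positive when the ratio exceeds
a threshold; the full Youden-point metric suite is computed on the
ROC, characterized under leave-one-out cross-validation as
median (IQR) across folds, and a pseudo-prospective variant fixes the
cut-off at 0.5 with no per-fold fitting.
"""

from __future__ import annotations

import logging

import numpy as np

from .localization import DegenerateLabelsError, build_roc
from .stats import barnard_test, rank_sum
from .types import (
    BiomarkerRates,
    ChannelInfo,
    ConfusionMatrix,
    OutcomeMetrics,
    PatientRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)


def resection_ratio(
    rates: BiomarkerRates, channels: list[ChannelInfo], category: str
) -> float | None:
    """Sum of resected-contact rates over the sum across all contacts.

    None (undefined) when the patient shows no event of the biomarker.
    """
    total = 0.0
    resected = 0.0
    for ch in channels:
        r = rates.rate(ch.channel_id, category)
        total += r
        if ch.is_resected:
            resected += r
    if total <= 0:
        return None
    return resected / total


def soz_ratio(channels: list[ChannelInfo]) -> float | None:
    """|SOZ and resected| / |SOZ|; None when no contact is SOZ."""
    soz = [c for c in channels if c.is_soz]
    if not soz:
        return None
    return sum(c.is_resected for c in soz) / len(soz)


def _predictor(pr: PatientRecord, category: str) -> float | None:
    if category.upper() == "SOZ":
        return soz_ratio(pr.channels)
    return resection_ratio(pr.rates, pr.channels, category)


def cohort_predictors(
    cohort: list[PatientRecord], category: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """(predictor values, good-outcome flags, n excluded) over patients
    with a defined predictor."""
    vals, labels = [], []
    excluded = 0
    for pr in cohort:
        v = _predictor(pr, category)
        if v is None:
            excluded += 1
            continue
        vals.append(v)
        labels.append(pr.good_outcome)
    return np.asarray(vals, float), np.asarray(labels, bool), excluded


def metrics_at_threshold(
    values: np.ndarray, labels: np.ndarray, threshold: float, auc: float, n_excluded=0
) -> OutcomeMetrics:
    """Metric suite with prediction = value > threshold (strict)."""
    pred = values > threshold
    cm = ConfusionMatrix(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )
    return OutcomeMetrics.from_confusion(cm, auc, threshold, n_excluded)


def outcome_roc_metrics(
    values, labels, n_excluded: int = 0
) -> OutcomeMetrics:
    """Youden-point metrics: positive class = good outcome, predicted
    positive when the ratio exceeds the fitted threshold.

    The threshold maximizing sensitivity + specificity - 1 is found by
    scanning every achievable operating point; ties resolve to the
    largest (most specific) threshold.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("need both good and poor outcomes")
    roc = build_roc(values, labels, positive_label="good")
    auc = roc.auc
    j = roc.sensitivity + roc.specificity - 1.0
    best = int(np.argmax(j))  # thresholds descend: first max = largest threshold
    thr = roc.thresholds[best]
    if not np.isfinite(thr):
        thr = float(values.max())
    return metrics_at_threshold(values, labels, float(thr), auc, n_excluded)


def outcome_table(
    cohort: list[PatientRecord], category: str
) -> tuple[OutcomeMetrics, np.ndarray, np.ndarray]:
    values, labels, excluded = cohort_predictors(cohort, category)
    if len(values) == 0:
        raise ValidationError(f"no patient has a defined {category} predictor")
    return outcome_roc_metrics(values, labels, excluded), values, labels


def association_with_outcome(
    cohort: list[PatientRecord], category: str, cutoff: float = 0.5
) -> dict:
    """Barnard's exact test of (ratio > cutoff) against outcome."""
    values, labels, excluded = cohort_predictors(cohort, category)
    pred = values > cutoff
    table = [
        [int(np.sum(pred & labels)), int(np.sum(pred & ~labels))],
        [int(np.sum(~pred & labels)), int(np.sum(~pred & ~labels))],
    ]
    return {
        "table": table,
        "p": barnard_test(table),
        "n": int(len(values)),
        "n_excluded": excluded,
    }


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _median_iqr(vals: list[float]) -> tuple[float, tuple[float, float]]:
    a = np.asarray(vals, float)
    return (
        float(np.median(a)),
        (float(np.percentile(a, 25)), float(np.percentile(a, 75))),
    )


def _loocv(values: np.ndarray, labels: np.ndarray, fold_metrics) -> dict:
    per_metric: dict[str, list[float]] = {}
    n_skipped = 0
    for i in range(len(values)):
        keep = np.ones(len(values), dtype=bool)
        keep[i] = False
        v, l = values[keep], labels[keep]
        if l.all() or not l.any():
            n_skipped += 1
            logger.info("LOO fold %d skipped: single-class", i)
            continue
        m = fold_metrics(v, l)
        for k, val in m.as_dict().items():
            per_metric.setdefault(k, []).append(val)
    if not per_metric:
        raise ValidationError("every LOO fold was degenerate")
    summary = {k: _median_iqr(v) for k, v in per_metric.items()}
    summary["n_folds"] = len(next(iter(per_metric.values())))
    summary["n_skipped"] = n_skipped
    return summary


def loocv_outcome(cohort: list[PatientRecord], category: str) -> dict:
    """Leave-one-out characterization of the Youden-point metrics.

    Each fold drops one patient and refits the optimal threshold on
    the remaining n-1; metrics are summarized as median (IQR) across
    folds. This characterizes the stability of the operating point, it
    is not held-out prediction of the dropped patient.
    """
    values, labels, excluded = cohort_predictors(cohort, category)
    if len(values) < 3:
        raise ValidationError("need >= 3 patients with a defined predictor")
    out = _loocv(values, labels, lambda v, l: outcome_roc_metrics(v, l))
    out["n_excluded"] = excluded
    return out


def pseudo_prospective(
    cohort: list[PatientRecord], category: str, cutoff: float = 0.5
) -> dict:
    """LOO-fold metrics at the fixed resection-ratio cut-off.

    Prediction is good outcome iff ratio > cutoff (strict: a ratio of
    exactly 0.5 predicts poor); no threshold is fitted anywhere.
    """
    values, labels, excluded = cohort_predictors(cohort, category)
    if len(values) < 3:
        raise ValidationError("need >= 3 patients with a defined predictor")

    def fold(v, l):
        roc = build_roc(v, l, positive_label="good")
        return metrics_at_threshold(v, l, cutoff, roc.auc)

    out = _loocv(values, labels, fold)
    out["n_excluded"] = excluded
    out["cutoff"] = cutoff
    return out


# ---------------------------------------------------------------------------
# subgroups and group contrasts
# ---------------------------------------------------------------------------

def subgroup_filter(
    cohort: list[PatientRecord], rule: str, spike_cut: float | None = None
) -> list[PatientRecord]:
    """Select the spike-rate patient subsets used in subgroup analyses.

    ``frequent_spikes``: median All_S channel rate above the cut-point
    (default: the cohort median, recomputed). ``no_fr_rare_spikes``:
    no fast-ripple events at all and median spike rate below the cut.
    """
    from .localization import median_spike_rate

    if rule not in ("frequent_spikes", "no_fr_rare_spikes"):
        raise ValidationError(f"unknown subgroup rule {rule!r}")
    if not cohort:
        return []
    med_rates = {pr.patient_id: median_spike_rate(pr) for pr in cohort}
    cut = (
        spike_cut
        if spike_cut is not None
        else float(np.median(list(med_rates.values())))
    )
    if rule == "frequent_spikes":
        return [pr for pr in cohort if med_rates[pr.patient_id] > cut]
    if rule == "no_fr_rare_spikes":
        out = []
        for pr in cohort:
            total_fr = float(np.sum(pr.rates.category_vector("All_FR")))
            if total_fr == 0 and med_rates[pr.patient_id] < cut:
                out.append(pr)
        return out
    raise ValidationError(f"unknown subgroup rule {rule!r}")


def compare_outcome_groups(
    cohort: list[PatientRecord], category: str, summary: str = "resection_ratio"
) -> dict:
    """Rank-sum contrast of a per-patient summary between good and poor
    outcome groups; summary is 'resection_ratio' or 'mean_rate'."""
    good, poor = [], []
    for pr in cohort:
        if summary == "resection_ratio":
            v = _predictor(pr, category)
            if v is None:
                continue
        elif summary == "mean_rate":
            v = float(np.mean(pr.rates.category_vector(category)))
        else:
            raise ValidationError(f"unknown summary {summary!r}")
        (good if pr.good_outcome else poor).append(v)
    if len(good) < 2 or len(poor) < 2:
        raise ValidationError("both outcome groups need >= 2 patients")
    stat, p = rank_sum(good, poor)
    return {
        "n_good": len(good),
        "n_poor": len(poor),
        "good_median": float(np.median(good)),
        "poor_median": float(np.median(poor)),
        "statistic": stat,
        "p": p,
    }
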