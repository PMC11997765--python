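"""SOZ / resected-area localization metrics.

Each iEEG contact is scored by its biomarker rate; contacts inside the
SOZ (or resection) are the condition-positive class. A contact is
predicted positive when its rate exceeds the threshold, and the ROC is
traced over all achievable thresholds. The figure of merit is the
partial AUC restricted to specificity 85–100%, normalized by the
maximum achievable restricted area (0.15), plus sensitivities read at
fixed specificity levels.

Two chance references exist for the normalized pAUC: 0.5 (half the
maximum, the convention used when reporting clinical cohorts) and
0.075 (the area actually swept by a diagonal no-skill ROC over
FPR in [0, 0.15]). Both are exposed; see CHANCE_LEVEL_HALF_MAX and
CHANCE_LEVEL_DIAGONAL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import kruskal_wallis_tukey, signed_rank, spearman
from .types import (
    BiomarkerRates,
    ChannelInfo,
    LocalizationScore,
    PatientRecord,
    ValidationError,
)

SPEC_RANGE = (0.85, 1.0)
SPEC_LEVELS = (0.85, 0.90, 0.95)

#: maximum restricted area over specificity 85-100%
PAUC_MAX = 0.15
#: half-max chance convention (normalized 0.5)
CHANCE_LEVEL_HALF_MAX = PAUC_MAX / 2.0
#: area of the true diagonal ROC over the restricted range (0.15^2 / 2)
CHANCE_LEVEL_DIAGONAL = PAUC_MAX**2 / 2.0


class DegenerateLabelsError(ValidationError):
    """Both classes must be present to trace a ROC."""


@dataclass
class RocCurve:
    """Operating points over descending thresholds.

    Predicted positive iff score > threshold; thresholds are the
    unique scores plus +inf, so the endpoints (sens, spec) = (0, 1)
    and (1, 0) are always present (all rates >= 0, and threshold -1
    captures everything).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_label: str = "inside"

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def auc(self) -> float:
        order = np.argsort(self.fpr, kind="stable")
        return float(np.trapezoid(self.sensitivity[order], self.fpr[order]))


def build_roc(values, labels, positive_label: str = "inside") -> RocCurve:
    """ROC of per-unit scores against boolean condition flags."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValidationError("values and labels must be 1-D and equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("need both positive and negative units")

    thresholds = np.concatenate([[np.inf], np.unique(values)[::-1]])
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, thr in enumerate(thresholds):
        pred = values > thr
        tp = int(np.sum(pred & labels))
        fp = int(np.sum(pred & ~labels))
        sens[i] = tp / n_pos
        spec[i] = (n_neg - fp) / n_neg
    # ensure the (1, 0) endpoint even when min(values) > 0
    if sens[-1] < 1.0 or spec[-1] > 0.0:
        thresholds = np.append(thresholds, thresholds[-1] - 1.0)
        sens = np.append(sens, 1.0)
        spec = np.append(spec, 0.0)
    return RocCurve(thresholds, sens, spec, positive_label)


def sens_at_spec(roc: RocCurve, levels=SPEC_LEVELS) -> dict[float, float]:
    """Sensitivity at the operating point with the smallest achievable
    specificity >= each level (no interpolation)."""
    out: dict[float, float] = {}
    for level in levels:
        ok = roc.specificity >= level - 1e-12
        if not ok.any():
            out[level] = 0.0
            continue
        spec_ok = roc.specificity[ok]
        sens_ok = roc.sensitivity[ok]
        smallest = spec_ok.min()
        out[level] = float(sens_ok[spec_ok <= smallest + 1e-12].max())
    return out


def partial_auc(roc: RocCurve, spec_range=SPEC_RANGE) -> LocalizationScore:
    """Trapezoidal sensitivity-over-FPR area on FPR in [0, 1-spec_lo].

    The ROC is linearly interpolated at the FPR boundary so the
    restricted area is exact for step curves.
    """
    fpr_hi = 1.0 - spec_range[0]
    # operating points in sweep order: thresholds descend, so FPR and
    # sensitivity are both nondecreasing; walk the empirical polyline
    # (vertical segments contribute zero width) and cut the segment
    # that straddles the FPR boundary by linear interpolation
    order = np.lexsort((roc.sensitivity, roc.fpr))
    fpr = roc.fpr[order]
    sens = roc.sensitivity[order]
    xs = [0.0]
    ys = [float(sens[0]) if fpr[0] <= 1e-15 else 0.0]
    for f, s in zip(fpr, sens):
        if f < fpr_hi + 1e-15:
            xs.append(float(min(f, fpr_hi)))
            ys.append(float(s))
        else:
            # first point beyond the boundary: interpolate on the
            # segment from the previous point
            x0, y0 = xs[-1], ys[-1]
            frac = (fpr_hi - x0) / (f - x0) if f > x0 else 0.0
            xs.append(fpr_hi)
            ys.append(y0 + frac * (s - y0))
            break
    if xs[-1] < fpr_hi:  # curve ends inside the window
        xs.append(fpr_hi)
        ys.append(ys[-1])
    raw = float(np.trapezoid(ys, xs))
    raw = min(max(raw, 0.0), PAUC_MAX)
    return LocalizationScore(
        pauc_raw=raw,
        pauc_norm=raw / PAUC_MAX,
        sens_at_spec=sens_at_spec(roc),
    )


# ---------------------------------------------------------------------------
# cohort-level analyses
# ---------------------------------------------------------------------------

def _region_flag(ch: ChannelInfo, region: str) -> bool:
    if region.upper() == "SOZ":
        return ch.is_soz
    if region.upper() == "RA":
        return ch.is_resected
    raise ValidationError("region must be 'SOZ' or 'RA'")


def channel_scores(
    rates: BiomarkerRates, channels: list[ChannelInfo], category: str, region: str
) -> tuple[np.ndarray, np.ndarray]:
    """(scores, labels) over a patient's contacts for one biomarker.

    Channels without events participate with rate 0.
    """
    ids = [c.channel_id for c in channels]
    scores = rates.category_vector(category, ids)
    labels = np.array([_region_flag(c, region) for c in channels], dtype=bool)
    return scores, labels


def pooled_roc(
    cohort: list[PatientRecord], category: str, region: str = "RA"
) -> RocCurve:
    """Group-level ROC pooling contacts across patients."""
    scores, labels = [], []
    for pr in cohort:
        s, l = channel_scores(pr.rates, pr.channels, category, region)
        scores.append(s)
        labels.append(l)
    return build_roc(np.concatenate(scores), np.concatenate(labels))


def patient_pauc(
    pr: PatientRecord, category: str, region: str = "RA"
) -> LocalizationScore | None:
    """Per-patient restricted pAUC; None when the patient's contacts
    are single-class (no SOZ/resected contacts, or all of them)."""
    scores, labels = channel_scores(pr.rates, pr.channels, category, region)
    try:
        roc = build_roc(scores, labels)
    except DegenerateLabelsError:
        return None
    return partial_auc(roc)


def compare_rates_in_out(
    cohort: list[PatientRecord],
    category: str,
    region: str = "RA",
    outcome_group: str | None = "good",
) -> dict:
    """Paired inside-vs-outside rate comparison.

    Per patient, the median channel rate over inside-region contacts
    and over outside contacts; Wilcoxon signed-rank across patients.
    Returns medians (IQR) per side and the two-sided p.
    """
    selected = [
        pr
        for pr in cohort
        if outcome_group is None or pr.outcome == outcome_group
    ]
    if len(selected) < 2:
        raise ValidationError("need >= 2 patients in the outcome group")
    inside, outside = [], []
    for pr in selected:
        scores, labels = channel_scores(pr.rates, pr.channels, category, region)
        if labels.all() or not labels.any():
            continue  # patient has no in/out contrast to contribute
        inside.append(float(np.median(scores[labels])))
        outside.append(float(np.median(scores[~labels])))
    if len(inside) < 2:
        raise ValidationError("fewer than 2 patients with both regions")
    stat, p = signed_rank(inside, outside)

    def med_iqr(v):
        v = np.asarray(v)
        return (
            float(np.median(v)),
            (float(np.percentile(v, 25)), float(np.percentile(v, 75))),
        )

    return {
        "n": len(inside),
        "inside_median_iqr": med_iqr(inside),
        "outside_median_iqr": med_iqr(outside),
        "statistic": stat,
        "p": p,
    }


def median_spike_rate(pr: PatientRecord) -> float:
    """Patient's median All_S channel rate (events/min)."""
    return float(np.median(pr.rates.category_vector("All_S")))


def correlate_pauc_spikerate(
    cohort: list[PatientRecord], category: str = "S+R", region: str = "RA"
) -> tuple[float, float]:
    """Spearman correlation between per-patient normalized pAUC of the
    category and the patient's median spike rate."""
    paucs, rates = [], []
    for pr in cohort:
        score = patient_pauc(pr, category, region)
        if score is None:
            continue
        paucs.append(score.pauc_norm)
        rates.append(median_spike_rate(pr))
    if len(paucs) < 5:
        raise ValidationError("need >= 5 patients with a defined pAUC")
    return spearman(rates, paucs)


def compare_groups_kw(values_by_group: dict[str, np.ndarray]) -> dict:
    """Kruskal-Wallis across groups with Tukey-Kramer-corrected
    pairwise post hoc (used for lobe and aetiology contrasts)."""
    return kruskal_wallis_tukey(values_by_group)
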