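"""ROC construction, restricted-specificity pAUC and the cohort-level
localization analyses, checked against brute-force and sklearn oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score, roc_curve

from hfomark.localization import (
    CHANCE_LEVEL_DIAGONAL,
    CHANCE_LEVEL_HALF_MAX,
    PAUC_MAX,
    DegenerateLabelsError,
    RocCurve,
    build_roc,
    compare_groups_kw,
    compare_rates_in_out,
    correlate_pauc_spikerate,
    partial_auc,
    patient_pauc,
    pooled_roc,
    sens_at_spec,
)
from hfomark.synth import CohortParams, SynthParams, synth_cohort
from hfomark.types import ValidationError


def brute_force_roc(values, labels):
    """Oracle: explicit confusion counts at every threshold."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    points = []
    for thr in np.concatenate([[np.inf], np.unique(values)[::-1], [values.min() - 1]]):
        pred = values > thr
        tp = np.sum(pred & labels)
        fp = np.sum(pred & ~labels)
        points.append((tp / labels.sum(), 1 - fp / (~labels).sum()))
    return points


def oracle_pauc(values, labels, fpr_hi=0.15):
    """Oracle: dense-grid integration of the sklearn ROC polyline
    clipped at fpr_hi."""
    fpr, tpr, _ = roc_curve(labels, values, drop_intermediate=False)
    grid = np.linspace(0.0, fpr_hi, 200001)
    sens = np.interp(grid, fpr, tpr)
    return np.trapezoid(sens, grid)


class TestBuildRoc:
    def test_perfect_separation(self):
        roc = build_roc([0, 1, 2, 3], [False, False, True, True])
        assert roc.auc == pytest.approx(1.0)
        assert np.any((roc.sensitivity == 1.0) & (roc.specificity == 1.0))

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            build_roc([1, 2], [True, True])

    def test_auc_equals_concordant_pair_count(self):
        values = [0, 1, 2, 3]
        labels = [False, True, False, True]
        # Mann-Whitney oracle: concordant pairs / all (pos, neg) pairs
        pos = [v for v, l in zip(values, labels) if l]
        neg = [v for v, l in zip(values, labels) if not l]
        pairs = [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
        assert build_roc(values, labels).auc == pytest.approx(np.mean(pairs))
        assert np.mean(pairs) == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 201))
        values = np.round(rng.uniform(0, 5, n), 1)  # force ties
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        roc = build_roc(values, labels)
        got = set(zip(np.round(roc.sensitivity, 12), np.round(roc.specificity, 12)))
        expected = {(round(s, 12), round(p, 12)) for s, p in brute_force_roc(values, labels)}
        assert got == expected
        assert roc.auc == pytest.approx(roc_auc_score(labels, values))


class TestSensAtSpec:
    def test_perfect_roc_all_ones(self):
        roc = build_roc([0, 1, 2, 3], [False, False, True, True])
        assert all(v == 1.0 for v in sens_at_spec(roc).values())

    def test_positive_below_all_negatives(self):
        roc = build_roc([0, 5, 6, 7], [True, False, False, False])
        assert all(v == 0.0 for v in sens_at_spec(roc).values())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_threshold_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        values = np.round(rng.uniform(0, 3, 200), 1)
        labels = rng.random(200) < 0.3
        roc = build_roc(values, labels)
        got = sens_at_spec(roc)
        neg = (~labels).sum()
        pos = labels.sum()
        for level, sens in got.items():
            best = None
            for thr in np.concatenate([[np.inf], np.unique(values)[::-1]]):
                pred = values > thr
                spec = 1 - np.sum(pred & ~labels) / neg
                if spec >= level:
                    cand = (spec, np.sum(pred & labels) / pos)
                    if best is None or cand[0] < best[0] or (
                        cand[0] == best[0] and cand[1] > best[1]
                    ):
                        best = cand
            assert sens == pytest.approx(best[1])


class TestPartialAuc:
    def test_perfect_classifier_reaches_max(self):
        roc = build_roc([0, 0, 1, 1], [False, False, True, True])
        score = partial_auc(roc)
        assert score.pauc_raw == pytest.approx(PAUC_MAX)
        assert score.pauc_norm == pytest.approx(1.0)

    def test_half_max_chance_convention(self):
        assert CHANCE_LEVEL_HALF_MAX == pytest.approx(0.075)
        assert CHANCE_LEVEL_HALF_MAX / PAUC_MAX == pytest.approx(0.5)

    def test_diagonal_roc_area_is_closed_form(self):
        x = np.linspace(0, 1, 1001)
        roc = RocCurve(
            thresholds=1 - x, sensitivity=x, specificity=1 - x
        )
        score = partial_auc(roc)
        assert score.pauc_raw == pytest.approx(0.15**2 / 2, abs=1e-6)
        assert score.pauc_raw == pytest.approx(CHANCE_LEVEL_DIAGONAL, abs=1e-6)
        assert score.pauc_norm == pytest.approx(0.075, abs=1e-4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_polyline_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(20, 200))
        values = np.round(rng.uniform(0, 4, n), 1)
        labels = rng.random(n) < 0.35
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        score = partial_auc(build_roc(values, labels))
        assert score.pauc_raw == pytest.approx(
            oracle_pauc(values, labels), abs=1e-6
        )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 2, 100)
        labels = rng.random(100) < 0.4
        a = partial_auc(build_roc(values, labels)).pauc_raw
        b = partial_auc(build_roc(np.exp(3 * values), labels)).pauc_raw
        assert a == pytest.approx(b)

    def test_bounds_always_hold(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            values = rng.uniform(0, 1, 50)
            labels = rng.random(50) < 0.5
            if labels.all() or not labels.any():
                continue
            s = partial_auc(build_roc(values, labels))
            assert 0 <= s.pauc_raw <= PAUC_MAX + 1e-12
            assert s.pauc_norm == pytest.approx(s.pauc_raw / PAUC_MAX)


class TestCohortAnalyses:
    def test_inside_elevation_detected(self, default_cohort):
        cohort, _ = default_cohort
        res = compare_rates_in_out(cohort, "All_S", "RA", "good")
        assert res["inside_median_iqr"][0] > res["outside_median_iqr"][0]
        assert res["p"] < 0.05

    def test_identical_in_out_gives_p_one(self):
        # rates constant across channels -> no inside/outside contrast
        from hfomark.cooccur import compute_rates
        from hfomark.types import ChannelInfo, PatientRecord

        cohort = []
        for pid in range(4):
            channels = [
                ChannelInfo(f"c{i}", is_resected=i < 2) for i in range(4)
            ]
            counts = {f"c{i}": {"All_S": 10} for i in range(4)}
            rates = compute_rates(counts, 10.0, [c.channel_id for c in channels])
            cohort.append(
                PatientRecord(f"P{pid}", rates, channels, engel="1a")
            )
        res = compare_rates_in_out(cohort, "All_S", "RA", "good")
        assert res["p"] == pytest.approx(1.0)

    def test_pauc_ranks_follow_injected_contrast(self, default_cohort):
        """The biomarker concentrated inside the resection (S+R, via the
        co-occurrence boost) localizes better than an unconcentrated one."""
        cohort, _ = default_cohort
        good = [pr for pr in cohort if pr.good_outcome]
        sr = np.median([patient_pauc(pr, "S+R").pauc_norm for pr in good])
        r_only = np.median([patient_pauc(pr, "R_only").pauc_norm for pr in good])
        assert sr > r_only

    def test_pooled_roc_beats_chance_on_structured_cohort(self, default_cohort):
        cohort, _ = default_cohort
        good = [pr for pr in cohort if pr.good_outcome]
        score = partial_auc(pooled_roc(good, "S+R", "RA"))
        assert score.pauc_norm > 0.5

    def test_correlation_perfect_monotone(self):
        from hfomark.stats import spearman

        rho, _ = spearman([1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60])
        assert rho == pytest.approx(1.0)

    def test_correlate_pauc_spikerate_runs(self, default_cohort):
        cohort, _ = default_cohort
        rho, p = correlate_pauc_spikerate(cohort, "S+R", "RA")
        assert -1 <= rho <= 1
        assert 0 <= p <= 1


class TestCompareGroupsKw:
    def test_identical_groups_no_effect(self):
        groups = {"a": np.arange(6.0), "b": np.arange(6.0), "c": np.arange(6.0)}
        res = compare_groups_kw(groups)
        # identical distributions: H small, p large, no pairwise finding
        assert res["p"] > 0.9
        assert all(p > 0.9 for p in res["pairwise"].values())

    def test_separated_groups_all_found(self):
        rng = np.random.default_rng(8)
        groups = {
            "a": rng.normal(0, 0.5, 10),
            "b": rng.normal(5, 0.5, 10),
            "c": rng.normal(10, 0.5, 10),
        }
        res = compare_groups_kw(groups)
        assert res["p"] < 1e-3
        assert all(p < 0.05 for p in res["pairwise"].values())

    def test_two_groups_match_h_oracle(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        res = compare_groups_kw({"a": a, "b": b})
        # direct rank-based H computation (no ties with continuous data)
        from scipy.stats import rankdata

        ranks = rankdata(np.concatenate([a, b]))
        n = len(ranks)
        h = 12 / (n * (n + 1)) * (
            ranks[:8].sum() ** 2 / 8 + ranks[8:].sum() ** 2 / 9
        ) - 3 * (n + 1)
        assert res["H"] == pytest.approx(h, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups_kw({"a": [1.0, 2.0], "b": []})
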