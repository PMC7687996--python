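"""Metric correctness against independent oracles and closed forms."""

import numpy as np
import pandas as pd
import pytest

from hypoforecast.evaluation import (
    auprc,
    auroc,
    brier,
    calibration,
    lead_time_curves,
    patient_level_auprc,
)


def pairwise_auroc(scores, labels):
    """Exhaustive positive/negative pair concordance, ties half credit."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def enumeration_auprc(scores, labels):
    """Average precision by explicit threshold enumeration: sum over
    descending unique thresholds of precision * recall increment."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = y.sum()
    ap, prev_recall = 0.0, 0.0
    for thr in sorted(set(s), reverse=True):
        sel = s >= thr
        precision = y[sel].mean()
        recall = y[sel].sum() / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_three_of_four_pairs_concordant(self):
        assert auroc([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0]) == 0.75

    def test_matches_pairwise_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 100))
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # rounding forces ties
            assert auroc(s, y) == pytest.approx(pairwise_auroc(s, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        s = rng.random(200)
        y = rng.integers(0, 2, 200)
        assert auroc(1 / (1 + np.exp(-7 * s)), y) == pytest.approx(auroc(s, y))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    def test_permutation_null_centred_on_half(self):
        rng = np.random.default_rng(2)
        s = rng.random(500)
        y = np.array([1] * 100 + [0] * 400)
        vals = []
        for _ in range(100):
            rng.shuffle(y)
            vals.append(auroc(s, y))
        assert 0.45 <= np.mean(vals) <= 0.55


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_uninformative_scores_give_prevalence(self):
        assert auprc([0.5, 0.5, 0.5, 0.5], [1, 0, 0, 0]) == pytest.approx(0.25)

    def test_one_positive_ranked_second(self):
        # descending scores: neg, POS, neg, neg -> AP = precision at rank 2 = 1/2
        assert auprc([0.4, 0.9, 0.2, 0.1], [1, 0, 0, 0]) == pytest.approx(0.5)

    def test_matches_enumeration_oracle_exactly(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(10, 100))
            y = rng.integers(0, 2, n)
            if y.sum() == 0:
                continue
            s = np.round(rng.random(n), 2)
            assert auprc(s, y) == pytest.approx(enumeration_auprc(s, y), abs=1e-12)

    def test_no_positives_raises(self):
        with pytest.raises(ValueError):
            auprc([0.1, 0.9], [0, 0])


class TestCalibration:
    def test_perfect_predictions_zero_brier(self):
        assert brier([1.0, 0.0, 1.0], [1, 0, 1]) == 0.0

    def test_constant_half_gives_quarter(self):
        assert brier([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0]) == pytest.approx(0.25)

    def test_constant_prevalence_gives_p_one_minus_p(self):
        y = np.array([1] * 3 + [0] * 9)  # prevalence 0.25
        assert brier(np.full(12, 0.25), y) == pytest.approx(0.25 * 0.75)

    def test_brier_not_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        s = rng.random(100)
        y = (s > 0.5).astype(int)
        assert brier(s, y) != pytest.approx(brier(s**3, y))

    def test_bin_counts_sum_to_sample_size(self):
        rng = np.random.default_rng(5)
        rep = calibration(rng.random(137), rng.integers(0, 2, 137))
        assert rep.bins["n"].sum() == 137
        assert len(rep.bins) == 10


class TestLeadTimeCurves:
    def _aligned(self, rng, n_per_group, informative=True):
        aligned, groups = {}, {}
        for i in range(n_per_group):
            lead = np.arange(0, 120)
            hi = np.clip(1 - lead / 100 + rng.normal(0, 0.05, len(lead)), 0, 1)
            lo = np.clip(0.1 + rng.normal(0, 0.05, len(lead)), 0, 1)
            if not informative:
                hi = rng.random(len(lead))
                lo = rng.random(len(lead))
            aligned[f"h{i}"] = pd.Series(hi, index=lead)
            aligned[f"n{i}"] = pd.Series(lo, index=lead)
            groups[f"h{i}"] = "hypotension"
            groups[f"n{i}"] = "non-hypotension"
        return aligned, groups

    def test_signal_grows_toward_onset(self):
        aligned, groups = self._aligned(np.random.default_rng(6), 20)
        curves = lead_time_curves(aligned, groups, [15, 60, 90])
        assert curves.set_index("lead_min").loc[15, "auroc"] >= curves.set_index(
            "lead_min"
        ).loc[60, "auroc"]

    def test_uninformative_scores_near_chance(self):
        aligned, groups = self._aligned(np.random.default_rng(7), 60, informative=False)
        curves = lead_time_curves(aligned, groups, [10, 50])
        assert ((curves["auroc"] - 0.5).abs() < 0.15).all()

    def test_grid_point_beyond_records_omitted(self):
        aligned, groups = self._aligned(np.random.default_rng(8), 5)
        curves = lead_time_curves(aligned, groups, [500])
        assert curves["auroc"].isna().all()
        assert (curves[["n_pos", "n_neg"]] == 0).all().all()

    def test_missing_minute_falls_back_within_tolerance(self):
        s = pd.Series([0.9], index=[16])  # nothing at lead 15, score at 16
        aligned = {"h0": s, "h1": pd.Series([0.8], index=[15]),
                   "n0": pd.Series([0.1], index=[15]), "n1": pd.Series([0.2], index=[15])}
        groups = {"h0": "hypotension", "h1": "hypotension",
                  "n0": "non-hypotension", "n1": "non-hypotension"}
        curves = lead_time_curves(aligned, groups, [15])
        assert curves["n_pos"].iloc[0] == 2  # h0 contributed via the fallback
        assert curves["auroc"].iloc[0] == 1.0


class TestPatientLevel:
    def _data(self, rng):
        scores, groups, onsets = {}, {}, {}
        for i in range(15):
            hid, nid = f"h{i}", f"n{i}"
            hs = np.clip(rng.normal(0.1, 0.05, 600), 0, 1)
            hs[520:580] = np.clip(rng.normal(0.8, 0.1, 60), 0, 1)
            scores[hid] = pd.Series(hs, index=np.arange(600))
            groups[hid] = "hypotension"
            onsets[hid] = 580
            ns = np.clip(rng.normal(0.12, 0.08, 600), 0, 1)
            scores[nid] = pd.Series(ns, index=np.arange(600))
            groups[nid] = "non-hypotension"
        return scores, groups, onsets

    def test_separable_maxima_give_one(self):
        scores = {"h0": pd.Series([0.9], index=[0]), "h1": pd.Series([0.8], index=[0]),
                  "n0": pd.Series([0.3], index=[0]), "n1": pd.Series([0.2], index=[0])}
        groups = {"h0": "hypotension", "h1": "hypotension",
                  "n0": "non-hypotension", "n1": "non-hypotension"}
        assert patient_level_auprc(scores, groups) == 1.0

    def test_random_hour_seeded_and_reproducible(self):
        scores, groups, onsets = self._data(np.random.default_rng(9))
        a = patient_level_auprc(scores, groups, "random-hour", onsets, seed=3)
        b = patient_level_auprc(scores, groups, "random-hour", onsets, seed=3)
        assert a == b

    def test_whole_stay_not_above_random_hour(self):
        # longer negative spans accrue more spurious peaks, so the
        # whole-stay variant cannot beat the focused one-hour variant here
        scores, groups, onsets = self._data(np.random.default_rng(10))
        whole = patient_level_auprc(scores, groups, "whole-stay", onsets, seed=3)
        hour = patient_level_auprc(scores, groups, "random-hour", onsets, seed=3)
        assert whole <= hour + 1e-9

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            patient_level_auprc({}, {}, mode="everything")
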