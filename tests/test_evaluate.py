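"""Median aggregation, ROC/Youden analysis and the confusion metric panel.

AUC and the Youden index are checked against exhaustive brute-force oracles
(all active/inactive pairs; a full threshold sweep) that share no code with
the implementation under test.
"""

import numpy as np
import pandas as pd
import pytest

from molsnap.evaluate import (MetricsReport, MoleculeScore, aggregate_median,
                              average_replicates, confusion_metrics,
                              evaluate_replicate, roc_auc, roc_points,
                              youden_cutoff)
from molsnap.fixtures import make_prediction_table


def _scores(actives, inactives):
    out = [MoleculeScore(f"a{i}", p, "active") for i, p in enumerate(actives)]
    out += [MoleculeScore(f"i{i}", p, "inactive")
            for i, p in enumerate(inactives)]
    return out


def _auc_bruteforce(scores):
    """Mann-Whitney over all (active, inactive) pairs: win 1, tie 1/2."""
    act = [s.median_probability for s in scores if s.label == "active"]
    ina = [s.median_probability for s in scores if s.label != "active"]
    total = 0.0
    for a in act:
        for b in ina:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(act) * len(ina))


def _youden_bruteforce(scores):
    """Max of TPR - FPR over every observed threshold (rule: >= cutoff)."""
    act = np.array([s.median_probability for s in scores
                    if s.label == "active"])
    ina = np.array([s.median_probability for s in scores
                    if s.label != "active"])
    best = -1.0
    for c in np.concatenate([act, ina, [max(act.max(), ina.max()) + 1]]):
        j = np.mean(act >= c) - np.mean(ina >= c)
        best = max(best, float(j))
    return best


class TestAggregateMedian:
    def test_odd_count_median(self):
        table = pd.DataFrame({
            "compound_id": ["m"] * 3, "label": ["active"] * 3,
            "probability_active": [0.1, 0.5, 0.9]})
        assert aggregate_median(table)[0].median_probability == 0.5

    def test_even_count_mean_of_central_pair(self):
        table = pd.DataFrame({
            "compound_id": ["m"] * 4, "label": ["inactive"] * 4,
            "probability_active": [0.2, 0.4, 0.6, 0.8]})
        assert aggregate_median(table)[0].median_probability == 0.5

    def test_constant_probabilities(self):
        table = pd.DataFrame({
            "compound_id": ["m"] * 27, "label": ["active"] * 27,
            "probability_active": [0.73] * 27})
        assert aggregate_median(table)[0].median_probability == 0.73

    def test_median_within_per_image_range(self):
        table = make_prediction_table(n_molecules=10, n_poses=9, seed=3)
        for score in aggregate_median(table):
            grp = table[table["compound_id"] == score.compound_id]
            assert (grp["probability_active"].min()
                    <= score.median_probability
                    <= grp["probability_active"].max())

    def test_conflicting_labels_rejected(self):
        table = pd.DataFrame({
            "compound_id": ["m", "m"], "label": ["active", "inactive"],
            "probability_active": [0.5, 0.5]})
        with pytest.raises(ValueError):
            aggregate_median(table)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(_scores([0.9, 0.8], [0.2, 0.1])) == 1.0

    def test_tied_example_pairwise(self):
        # pairs: (0.9>0.6)=1, (0.9>0.2)=1, (0.6=0.6)=0.5, (0.6>0.2)=1
        assert roc_auc(_scores([0.9, 0.6], [0.6, 0.2])) == pytest.approx(0.875)

    def test_chance_level_for_independent_labels(self):
        rng = np.random.default_rng(0)
        scores = _scores(rng.random(500), rng.random(500))
        assert roc_auc(scores) == pytest.approx(0.5, abs=0.06)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([MoleculeScore("a", 0.5, "active")])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_act = int(rng.integers(5, 100))
        n_ina = int(rng.integers(5, 100))
        # quantized scores force plenty of ties
        scores = _scores(np.round(rng.random(n_act), 2),
                         np.round(rng.random(n_ina), 2))
        assert roc_auc(scores) == pytest.approx(_auc_bruteforce(scores),
                                                abs=1e-12)


class TestYoudenCutoff:
    def test_perfect_separation_j_is_1(self):
        cutoff, j = youden_cutoff(_scores([0.9, 0.8], [0.2, 0.1]))
        assert j == 1.0
        assert 0.2 < cutoff <= 0.8

    def test_no_discrimination_j_is_0(self):
        cutoff, j = youden_cutoff(_scores([0.5, 0.5], [0.5, 0.5]))
        assert j == 0.0

    def test_separating_threshold_found(self):
        # min active 0.8 > max inactive 0.7: the sweep finds the separator
        cutoff, j = youden_cutoff(_scores([0.9, 0.8], [0.3, 0.7]))
        assert j == 1.0
        assert 0.7 < cutoff <= 0.8

    def test_overlapping_classes(self):
        # sweep by hand: cutoff 0.6 gives TPR 1, FPR 0.5, J = 0.5 (max)
        cutoff, j = youden_cutoff(_scores([0.9, 0.6], [0.7, 0.2]))
        assert j == pytest.approx(0.5)
        assert cutoff == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_threshold_sweep_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = _scores(np.round(rng.random(40), 2),
                         np.round(rng.random(160), 2))
        _, j = youden_cutoff(scores)
        assert j == pytest.approx(_youden_bruteforce(scores), abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        rep = confusion_metrics(_scores([0.9] * 5, [0.1] * 5), cutoff=0.5)
        assert (rep.mcc, rep.bac, rep.f_measure, rep.acc_percent) == \
            (1.0, 1.0, 1.0, 100.0)

    def test_hand_computed_confusion_panel(self):
        # TP=3, FP=1, TN=4, FN=2 at cutoff 0.5
        scores = _scores([0.9, 0.9, 0.9, 0.1, 0.1],
                         [0.9, 0.1, 0.1, 0.1, 0.1])
        rep = confusion_metrics(scores, cutoff=0.5)
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (3, 1, 4, 2)
        assert rep.acc_percent == pytest.approx(70.0)
        assert rep.bac == pytest.approx(0.7)
        assert rep.f_measure == pytest.approx(2.0 / 3.0)
        assert rep.mcc == pytest.approx(10.0 / np.sqrt(600.0))

    def test_zero_precision_sentinels(self):
        rep = confusion_metrics(_scores([0.1, 0.2], [0.05, 0.15]), cutoff=0.9)
        assert rep.f_measure == 0.0
        assert rep.mcc == 0.0

    def test_counts_conserved(self):
        table = make_prediction_table(n_molecules=30, seed=7)
        rep = evaluate_replicate(table)
        assert rep.tp + rep.fn == 15
        assert rep.tn + rep.fp == 15

    def test_cutoff_ties_predicted_active(self):
        rep = confusion_metrics(_scores([0.5], [0.4]), cutoff=0.5)
        assert rep.tp == 1 and rep.fn == 0

    def test_label_swap_symmetry(self):
        """Inverting labels and scores (p -> 1-p) preserves AUC, BAC and
        the MCC magnitude."""
        rng = np.random.default_rng(42)
        scores = _scores(rng.random(20) * 0.6 + 0.3, rng.random(30) * 0.6)
        rep = confusion_metrics(scores)
        swapped = [MoleculeScore(s.compound_id, 1.0 - s.median_probability,
                                 "inactive" if s.label == "active"
                                 else "active") for s in scores]
        rep_sw = confusion_metrics(swapped)
        assert rep_sw.auc == pytest.approx(rep.auc, abs=1e-12)
        assert rep_sw.youden_j == pytest.approx(rep.youden_j, abs=1e-12)
        assert abs(rep_sw.mcc) == pytest.approx(abs(rep.mcc), abs=1e-9)

    def test_bac_equals_acc_when_balanced_and_symmetric(self):
        scores = _scores([0.9, 0.9, 0.2], [0.8, 0.1, 0.1])
        rep = confusion_metrics(scores, cutoff=0.5)
        assert rep.bac * 100 == pytest.approx(rep.acc_percent)


class TestAverageReplicates:
    def test_single_report_zero_se(self):
        rep = confusion_metrics(_scores([0.9], [0.1]))
        df = average_replicates([rep]).set_index("metric")
        assert df.loc["auc", "mean"] == 1.0
        assert df.loc["auc", "se"] == 0.0

    def test_two_point_mean_and_se(self):
        a = confusion_metrics(_scores([0.9], [0.1]))
        b = MetricsReport(**{**a.__dict__, "auc": 0.8})
        a = MetricsReport(**{**a.__dict__, "auc": 0.9})
        df = average_replicates([a, b]).set_index("metric")
        assert df.loc["auc", "mean"] == pytest.approx(0.85)
        assert df.loc["auc", "se"] == pytest.approx(0.05)

    def test_identical_reports_zero_se(self):
        rep = confusion_metrics(_scores([0.9, 0.4], [0.5, 0.1]))
        df = average_replicates([rep, rep, rep])
        assert df["se"].abs().max() < 1e-12


class TestRocPoints:
    def test_curve_spans_unit_square(self):
        table = make_prediction_table(n_molecules=20, seed=5)
        pts = roc_points(aggregate_median(table))
        assert pts["fpr"].iloc[0] == 0.0
        assert pts["tpr"].iloc[-1] == 1.0
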