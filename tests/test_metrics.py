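"""Metric formulas against independent oracles; curve sweeps; operon matching."""

import math

import numpy as np
import pytest

from operonvision.assembly import OperonPrediction
from operonvision.io import OperonRecord
from operonvision.metrics import (
    ConfusionCounts,
    MetricsError,
    compute_metrics,
    confusion_from_rates,
    curves,
    exact_operon_matches,
)


def _oracle_rates(tp, fp, fn, tn):
    """Textbook confusion-matrix formulas, coded independently."""
    sens = tp / (tp + fn)
    prec = tp / (tp + fp)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + fp + fn + tn)
    mcc = (tp * tn - fp * fn) / math.sqrt(
        (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    f1 = 2 * sens * prec / (sens + prec)
    return sens, prec, spec, acc, mcc, f1


class TestComputeMetrics:
    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(TP=10, FP=0, FN=0, TN=10))
        assert (r.sensitivity, r.precision, r.specificity) == (1.0, 1.0, 1.0)
        assert (r.accuracy, r.mcc, r.f1) == (1.0, 1.0, 1.0)
        assert not r.mcc_degenerate

    def test_oracle_equivalence_500_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 500, size=4))
            r = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
            sens, prec, spec, acc, mcc, f1 = _oracle_rates(tp, fp, fn, tn)
            assert r.sensitivity == pytest.approx(sens, abs=1e-12)
            assert r.precision == pytest.approx(prec, abs=1e-12)
            assert r.specificity == pytest.approx(spec, abs=1e-12)
            assert r.accuracy == pytest.approx(acc, abs=1e-12)
            assert r.mcc == pytest.approx(mcc, abs=1e-12)
            assert r.f1 == pytest.approx(f1, abs=1e-12)

    def test_accuracy_identity(self):
        """accuracy == (sens*P + spec*N) / (P + N), algebraically."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 200, size=4))
            r = compute_metrics(ConfusionCounts(tp, fp, fn, tn))
            P, N = tp + fn, tn + fp
            assert r.accuracy == pytest.approx(
                (r.sensitivity * P + r.specificity * N) / (P + N), abs=1e-12
            )

    def test_mcc_symmetric_under_class_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 200, size=4))
            a = compute_metrics(ConfusionCounts(tp, fp, fn, tn)).mcc
            b = compute_metrics(ConfusionCounts(tn, fn, fp, tp)).mcc
            assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_mcc_is_zero_and_flagged(self):
        r = compute_metrics(ConfusionCounts(TP=0, FP=0, FN=5, TN=5))
        assert r.mcc == 0.0 and r.mcc_degenerate

    def test_undefined_precision_is_nan(self):
        r = compute_metrics(ConfusionCounts(TP=0, FP=0, FN=5, TN=5))
        assert math.isnan(r.precision)
        assert math.isnan(r.f1)

    def test_counts_validation(self):
        with pytest.raises(MetricsError):
            ConfusionCounts(-1, 0, 0, 5)
        with pytest.raises(MetricsError):
            ConfusionCounts(0, 0, 0, 0)


def test_confusion_from_rates_reconstruction():
    c = confusion_from_rates(0.92, 0.92, n_positive=730, n_negative=763)
    assert (c.TP, c.FN, c.TN, c.FP) == (672, 58, 702, 61)


def _auc_concordance(y, p):
    """Brute-force pairwise concordance (Mann-Whitney) oracle."""
    pos = [pi for yi, pi in zip(y, p) if yi]
    neg = [pi for yi, pi in zip(y, p) if not yi]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestCurves:
    def test_perfect_separation(self):
        y = [1, 1, 1, 0, 0, 0]
        p = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        _, _, roc_auc, pr_auc = curves(y, p)
        assert roc_auc == pytest.approx(1.0)
        assert pr_auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        y = [1, 0, 1, 0]
        _, _, roc_auc, _ = curves(y, [0.5] * 4)
        assert roc_auc == pytest.approx(0.5)

    def test_concordance_oracle_200_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                y[0], y[-1] = 0, 1
            # quantized scores force ties to be exercised
            p = np.round(rng.random(n), 1)
            _, _, roc_auc, _ = curves(y, p)
            assert roc_auc == pytest.approx(_auc_concordance(y, p), abs=1e-9)

    def test_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=100)
        y[0], y[1] = 0, 1
        p = rng.random(100)
        _, _, roc_auc, _ = curves(y, p)
        assert roc_auc == pytest.approx(roc_auc_score(y, p), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        p = rng.random(50)
        _, _, auc1, _ = curves(y, p)
        _, _, auc2, _ = curves(y, np.exp(3 * p))
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_is_an_error(self):
        with pytest.raises(MetricsError, match="both classes"):
            curves([1, 1, 1], [0.2, 0.3, 0.4])

    def test_roc_endpoints(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, size=30)
        y[0], y[1] = 0, 1
        roc, pr, _, _ = curves(y, rng.random(30))
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)
        assert np.all((roc >= 0) & (roc <= 1))
        assert np.all((pr >= 0) & (pr <= 1))


def _pred(gene_ids, genome="G", contig="c1"):
    return OperonPrediction(genome, contig, tuple(gene_ids), 0.9)


class TestExactOperonMatches:
    def test_identical_predictions_full_match(self):
        truth = [OperonRecord("G", ("g1", "g2", "g3")), OperonRecord("G", ("g5", "g6"))]
        preds = [_pred(["g1", "g2", "g3"]), _pred(["g5", "g6"])]
        assert exact_operon_matches(preds, truth) == 1.0

    def test_extension_by_one_gene_unmatched(self):
        truth = [OperonRecord("G", ("g1", "g2", "g3"))]
        assert exact_operon_matches([_pred(["g1", "g2", "g3", "g4"])], truth) == 0.0

    def test_merged_prediction_matches_neither(self):
        truth = [OperonRecord("G", ("g1", "g2")), OperonRecord("G", ("g3", "g4"))]
        merged = [_pred(["g1", "g2", "g3", "g4"])]
        assert exact_operon_matches(merged, truth) == 0.0

    def test_single_gene_truth_excluded(self):
        truth = [OperonRecord("G", ("g1",)), OperonRecord("G", ("g2", "g3"))]
        assert exact_operon_matches([_pred(["g2", "g3"])], truth) == 1.0

    def test_empty_truth_is_an_error(self):
        with pytest.raises(MetricsError):
            exact_operon_matches([], [OperonRecord("G", ("g1",))])

    def test_strand_orientation_ignored_via_gene_order(self):
        truth = [OperonRecord("G", ("g3", "g2"))]  # listed in transcription order
        order = {"g2": 0, "g3": 1}
        assert exact_operon_matches([_pred(["g2", "g3"])], truth, gene_order=order) == 1.0

    def test_random_last_gene_dropout_simulation(self):
        """Dropping each truth operon's last gene with prob p leaves a match
        fraction of about 1 - p over 1000 replicates."""
        rng = np.random.default_rng(8)
        p_drop = 0.3
        fractions = []
        truth = [
            OperonRecord("G", tuple(f"op{i}g{j}" for j in range(3))) for i in range(20)
        ]
        for _ in range(1000):
            preds = []
            for op in truth:
                ids = list(op.gene_ids)
                if rng.random() < p_drop:
                    ids = ids[:-1]
                preds.append(_pred(ids))
            fractions.append(exact_operon_matches(preds, truth))
        assert np.mean(fractions) == pytest.approx(1 - p_drop, abs=0.02)
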