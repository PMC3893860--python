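import math

import numpy as np
import pytest

from il4kit.evaluation import (
    ConfusionCounts,
    confusion_at,
    cross_validate,
    make_folds,
    metrics,
    roc_auc,
    threshold_sweep,
)
from il4kit.model import IL4Model, PredictionResult, SVMConfig
from il4kit.peptide_io import ValidationError

from conftest import make_dataset, random_peptide


def result(label, score, pid="x", adj=0):
    return PredictionResult(
        id=pid,
        sequence="ACDEFGHI",
        label=label,
        svm_score=score,
        motif_adjustment=adj,
        hybrid_score=score + adj,
        predicted_label="positive",
        threshold_used=0.0,
    )


def random_results(rng, n=40):
    return [
        result(
            "positive" if rng.random() < 0.5 else "negative",
            float(rng.normal()),
            pid=f"r{i}",
        )
        for i in range(n)
    ]


class TestFolds:
    def test_exact_divisibility(self, rng):
        pos = make_dataset([random_peptide(rng) for _ in range(10)], "positive", "p")
        neg = make_dataset([random_peptide(rng) for _ in range(10)], "negative", "n")
        pf, nf = make_folds(pos, neg, k=5, seed=3)
        assert np.bincount(pf).tolist() == [2] * 5
        assert np.bincount(nf).tolist() == [2] * 5

    def test_same_seed_reproduces_assignment(self, rng):
        pos = make_dataset([random_peptide(rng) for _ in range(23)], "positive", "p")
        neg = make_dataset([random_peptide(rng) for _ in range(17)], "negative", "n")
        a = make_folds(pos, neg, k=5, seed=11)
        b = make_folds(pos, neg, k=5, seed=11)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_reference_dataset_sizes(self, rng):
        """904 positives / 742 negatives split fivefold: per-class fold sizes
        must be ceil/floor of n/5 ({180,181} and {148,149})."""
        pos = make_dataset([random_peptide(rng) for _ in range(904)], "positive", "p")
        neg = make_dataset([random_peptide(rng) for _ in range(742)], "negative", "n")
        pf, nf = make_folds(pos, neg, k=5, seed=42)
        assert sorted(np.bincount(pf).tolist()) == [180, 181, 181, 181, 181]
        assert sorted(np.bincount(nf).tolist()) == [148, 148, 148, 149, 149]

    def test_class_smaller_than_k_rejected(self, rng):
        small = make_dataset([random_peptide(rng) for _ in range(3)], "positive", "p")
        big = make_dataset([random_peptide(rng) for _ in range(10)], "negative", "n")
        with pytest.raises(ValidationError):
            make_folds(small, big, k=5, seed=0)


class TestConfusionAndMetrics:
    def test_all_positive_above_threshold(self):
        rs = [result("positive", 1.0, pid=str(i)) for i in range(5)]
        c = confusion_at(rs, 0.0)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 0, 0)

    def test_threshold_above_max_score(self):
        rs = [result("positive", 0.1), result("negative", 0.2)]
        c = confusion_at(rs, 5.0)
        assert c.tp == 0 and c.fp == 0 and c.fn == 1 and c.tn == 1

    def test_ties_count_as_positive(self):
        rs = [result("negative", 0.3)]
        assert confusion_at(rs, 0.3).fp == 1

    def test_matches_bruteforce_tally(self, rng):
        rs = random_results(rng)
        t = 0.25
        c = confusion_at(rs, t)
        tp = sum(r.label == "positive" and r.svm_score >= t for r in rs)
        fp = sum(r.label == "negative" and r.svm_score >= t for r in rs)
        fn = sum(r.label == "positive" and r.svm_score < t for r in rs)
        tn = sum(r.label == "negative" and r.svm_score < t for r in rs)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_unlabeled_rejected(self):
        with pytest.raises(ValidationError):
            confusion_at([result("unlabeled", 0.5)], 0.0)

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert m == {
            "sensitivity": 100.0,
            "specificity": 100.0,
            "accuracy": 100.0,
            "mcc": 1.0,
        }

    def test_inverted_classifier(self):
        m = metrics(ConfusionCounts(tp=0, fp=50, tn=0, fn=50))
        assert m["accuracy"] == 0.0
        assert m["mcc"] == -1.0

    def test_hand_computed_case(self):
        # tp=30 fn=10 tn=20 fp=40: Sen 75, Spec 33.33, Acc 50,
        # MCC = (30*20-40*10)/sqrt(70*40*60*30) = 200/2244.994... = 0.0890871
        m = metrics(ConfusionCounts(tp=30, fp=40, tn=20, fn=10))
        assert m["sensitivity"] == pytest.approx(75.0)
        assert m["specificity"] == pytest.approx(100.0 / 3)
        assert m["accuracy"] == pytest.approx(50.0)
        assert m["mcc"] == pytest.approx(0.0890871, abs=1e-6)

    def test_zero_denominator_mcc_is_zero(self):
        assert metrics(ConfusionCounts(tp=10, fp=10, tn=0, fn=0))["mcc"] == 0.0

    def test_absent_class_reported_missing(self):
        m = metrics(ConfusionCounts(tp=5, fp=0, tn=0, fn=0))
        assert math.isnan(m["specificity"])
        assert m["sensitivity"] == 100.0

    def test_random_tables_match_closed_forms(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(0, 60, size=4))
            if tp + fp + tn + fn == 0:
                continue
            m = metrics(ConfusionCounts(tp, fp, tn, fn))
            assert -1.0 <= m["mcc"] <= 1.0
            assert m["accuracy"] == pytest.approx(100 * (tp + tn) / (tp + fp + tn + fn))


class TestSweep:
    def test_single_threshold_single_row(self, rng):
        sw = threshold_sweep(random_results(rng), thresholds=[0.0])
        assert len(sw.table) == 1

    def test_monotonicity(self, rng):
        sw = threshold_sweep(random_results(rng, 80))
        sen = sw.table["sensitivity"].to_numpy()
        spe = sw.table["specificity"].to_numpy()
        assert (np.diff(sen) <= 1e-9).all()
        assert (np.diff(spe) >= -1e-9).all()

    def test_composition_equals_pointwise_calls(self, rng):
        rs = random_results(rng)
        sw = threshold_sweep(rs)
        for _, row in sw.table.iterrows():
            m = metrics(confusion_at(rs, row["threshold"]))
            assert row["mcc"] == pytest.approx(m["mcc"])
            assert row["accuracy"] == pytest.approx(m["accuracy"])

    def test_best_row_maximises_mcc(self, rng):
        sw = threshold_sweep(random_results(rng, 60))
        assert sw.best["mcc"] == pytest.approx(sw.table["mcc"].max())


class TestROC:
    def test_perfect_separation(self):
        rs = [result("positive", 2.0, pid="a"), result("negative", -2.0, pid="b")]
        assert roc_auc(rs) == 1.0

    def test_all_tied_gives_half(self):
        rs = [result("positive", 0.5, pid="a"), result("negative", 0.5, pid="b")]
        assert roc_auc(rs) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        rs = random_results(rng, 20)
        pos = [r.svm_score for r in rs if r.label == "positive"]
        neg = [r.svm_score for r in rs if r.label == "negative"]
        u = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert roc_auc(rs) == pytest.approx(u / (len(pos) * len(neg)))

    def test_invariant_under_monotone_transform(self, rng):
        rs = random_results(rng, 30)
        transformed = [
            result(r.label, math.exp(r.svm_score) + 3, pid=r.id) for r in rs
        ]
        assert roc_auc(rs) == pytest.approx(roc_auc(transformed))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([result("positive", 1.0)])


class TestCrossValidate:
    def test_every_peptide_tested_exactly_once(self, rng):
        pos = make_dataset([random_peptide(rng) for _ in range(25)], "positive", "p")
        neg = make_dataset([random_peptide(rng) for _ in range(20)], "negative", "n")
        rep = cross_validate(pos, neg, SVMConfig("rbf", 0.01, 1.0, 1.0, "AAC"), seed=5)
        ids = [r.id for r in rep.results]
        assert sorted(ids) == sorted(pos.ids() + neg.ids())
        assert set(rep.fold_of.values()) == set(range(5))

    def test_two_fold_matches_manual_runs(self, rng):
        pos = make_dataset([random_peptide(rng) for _ in range(12)], "positive", "p")
        neg = make_dataset([random_peptide(rng) for _ in range(12)], "negative", "n")
        cfg = SVMConfig("rbf", 0.01, 1.0, 1.0, "AAC")
        rep = cross_validate(pos, neg, cfg, k=2, seed=9)
        pf, nf = make_folds(pos, neg, k=2, seed=9)
        manual = {}
        for f in (0, 1):
            fitted = IL4Model(
                pos.subset(np.nonzero(pf != f)[0]),
                neg.subset(np.nonzero(nf != f)[0]),
                cfg,
            ).fit(seed=9)
            for ds, folds in ((pos, pf), (neg, nf)):
                test = ds.subset(np.nonzero(folds == f)[0])
                for r in fitted.score(test):
                    manual[r.id] = r.svm_score
        for r in rep.results:
            assert manual[r.id] == pytest.approx(r.svm_score, abs=1e-12)

    def test_sweep_monotonicity_holds_on_cv_output(self, rng):
        pos = make_dataset([random_peptide(rng) for _ in range(30)], "positive", "p")
        neg = make_dataset([random_peptide(rng) for _ in range(30)], "negative", "n")
        rep = cross_validate(pos, neg, SVMConfig("rbf", 0.01, 1.0, 1.0, "AAC"), seed=2)
        sen = rep.pooled.table["sensitivity"].to_numpy()
        spe = rep.pooled.table["specificity"].to_numpy()
        assert (np.diff(sen) <= 1e-9).all()
        assert (np.diff(spe) >= -1e-9).all()

    def test_report_serialisation(self, rng, tmp_path):
        import json

        pos = make_dataset([random_peptide(rng) for _ in range(15)], "positive", "p")
        neg = make_dataset([random_peptide(rng) for _ in range(15)], "negative", "n")
        rep = cross_validate(pos, neg, SVMConfig("rbf", 0.01, 1.0, 1.0, "AAC"), seed=1)
        rep.to_tsv(tmp_path / "sweep.tsv")
        rep.to_json(tmp_path / "rep.json")
        payload = json.loads((tmp_path / "rep.json").read_text())
        assert len(payload["pooled"]) == 21
        assert payload["k"] == 5
        assert "roc_auc" in payload
        assert (tmp_path / "sweep.tsv").read_text().startswith("threshold")

    def test_fold_mean_table_shape(self, rng):
        pos = make_dataset([random_peptide(rng) for _ in range(20)], "positive", "p")
        neg = make_dataset([random_peptide(rng) for _ in range(20)], "negative", "n")
        rep = cross_validate(pos, neg, SVMConfig("rbf", 0.01, 1.0, 1.0, "AAC"), seed=4)
        fm = rep.fold_mean()
        assert list(fm.columns) == ["threshold", "sensitivity", "specificity", "accuracy", "mcc"]
        assert len(fm) == 21
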