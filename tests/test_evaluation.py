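import math

import numpy as np
import pytest

from druggability import (
    ConfusionCounts,
    DNNConfig,
    classification_metrics,
    compute_all_metrics,
    confusion,
    cross_validate,
    default_pipeline_factory,
    dkl,
    independent_test,
    jm_distance,
    jm_report,
    lift_curve,
    random_label_null,
    ranking_metrics,
)
from druggability.records import DatasetManifest


# --------------------------------------------------------------------------
# Independent brute-force oracles
# --------------------------------------------------------------------------

def auc_by_pairwise_concordance(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def kappa_direct(tp, fp, tn, fn):
    n = tp + fp + tn + fn
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    return (po - pe) / (1 - pe)


def mcc_direct(tp, fp, tn, fn):
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / den


# the 120-protein fixture has ~3 minibatches per epoch, so give the head a
# higher learning rate and more patience than the large-data defaults
FAST_NET = DNNConfig(max_epochs=60, early_stop_patience=10, lr_initial=2e-3)


class TestConfusion:
    def test_basic_counts(self):
        c = confusion(np.array([0.9, 0.1]), np.array([1, 0]))
        assert (c.TP, c.TN, c.FP, c.FN) == (1, 1, 0, 0)

    def test_score_at_threshold_counts_positive(self):
        c = confusion(np.array([0.5]), np.array([0]))
        assert c.FP == 1

    def test_all_missed(self):
        c = confusion(np.zeros(5), np.ones(5))
        assert c.FN == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(3), np.zeros(2))


class TestClassificationMetrics:
    def test_worked_confusion_matrix(self):
        m = classification_metrics(ConfusionCounts(TP=90, FN=10, TN=80, FP=20))
        assert m["precision"] == pytest.approx(0.8182, abs=5e-5)
        assert m["recall"] == pytest.approx(0.9000, abs=5e-5)
        assert m["specificity"] == pytest.approx(0.8000, abs=5e-5)
        assert m["accuracy"] == pytest.approx(0.8500, abs=5e-5)
        assert m["npv"] == pytest.approx(0.8889, abs=5e-5)
        assert m["f1"] == pytest.approx(0.8571, abs=5e-5)
        assert m["mcc"] == pytest.approx(0.7035, abs=5e-5)
        assert m["kappa"] == pytest.approx(0.7000, abs=5e-5)
        assert m["dor"] == pytest.approx(36.0, abs=5e-5)
        assert m["dp"] == pytest.approx(1.9757, abs=5e-5)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(TP=50, FN=0, TN=50, FP=0))
        assert m["mcc"] == pytest.approx(1.0)
        assert m["kappa"] == pytest.approx(1.0)

    def test_no_information_point(self):
        m = classification_metrics(ConfusionCounts(TP=25, FN=25, TN=25, FP=25))
        assert m["mcc"] == pytest.approx(0.0)
        assert m["kappa"] == pytest.approx(0.0)
        assert m["dor"] == pytest.approx(1.0)
        assert m["dp"] == pytest.approx(0.0)

    def test_zero_cell_uses_haldane_correction_for_dor_only(self):
        m = classification_metrics(ConfusionCounts(TP=10, FN=0, TN=10, FP=5))
        assert m["dor"] == pytest.approx((10.5 * 10.5) / (5.5 * 0.5))
        assert m["recall"] == 1.0  # rate metrics uncorrected

    def test_undefined_rates_reported_as_nan(self):
        m = classification_metrics(ConfusionCounts(TP=0, FN=0, TN=10, FP=0))
        assert math.isnan(m["recall"])
        assert math.isnan(m["precision"])

    def test_oracle_agreement_on_random_confusions(self, rng):
        for _ in range(1000):
            tp, fp, tn, fn = rng.integers(1, 200, size=4)
            m = classification_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
            assert m["kappa"] == pytest.approx(kappa_direct(tp, fp, tn, fn), abs=1e-12)
            assert m["mcc"] == pytest.approx(mcc_direct(tp, fp, tn, fn), abs=1e-12)
            assert m["dor"] == pytest.approx((tp * tn) / (fp * fn), abs=1e-9)
            assert m["dp"] == pytest.approx(
                math.sqrt(3) / math.pi * math.log(tp * tn / (fp * fn)), abs=1e-9
            )


class TestRankingMetrics:
    def test_perfect_separation(self):
        r = ranking_metrics(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 1, 0, 0]))
        assert r["auc"] == 1.0

    def test_three_of_four_concordant_pairs(self):
        r = ranking_metrics(np.array([0.9, 0.4, 0.6, 0.2]), np.array([1, 1, 0, 0]))
        assert r["auc"] == pytest.approx(0.75)

    def test_constant_scores_give_half(self):
        r = ranking_metrics(np.full(10, 0.3), np.array([1, 0] * 5))
        assert r["auc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ranking_metrics(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_oracle_agreement_on_random_scorings(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 60))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            auc = ranking_metrics(scores, labels)["auc"]
            assert auc == pytest.approx(auc_by_pairwise_concordance(scores, labels), abs=1e-12)

    def test_invariance_under_monotone_transform(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        a = ranking_metrics(scores, labels)["auc"]
        b = ranking_metrics(np.exp(3 * scores) + 7, labels)["auc"]
        assert a == pytest.approx(b, abs=1e-12)


class TestDkl:
    def test_zero_when_distributions_match(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.7, 0.3, 0.6, 0.4])  # mean 0.5 = prevalence
        assert dkl(labels, scores) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        labels = np.array([1] * 5 + [0] * 5)
        scores = np.full(10, 0.6)
        expected = 0.5 * math.log(0.5 / 0.6) + 0.5 * math.log(0.5 / 0.4)
        assert dkl(labels, scores) == pytest.approx(expected, abs=1e-12)
        assert dkl(labels, scores) == pytest.approx(0.02041, abs=1e-5)

    def test_grows_as_mean_score_collapses(self):
        labels = np.array([1] * 5 + [0] * 5)
        vals = [dkl(labels, np.full(10, q)) for q in (0.5, 0.1, 1e-6, 1e-10)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestLift:
    def test_all_positives_in_top_decile(self):
        labels = np.array([1] * 10 + [0] * 90)
        scores = np.linspace(1, 0, 100)
        lifts = lift_curve(scores, labels, n_bins=10)
        assert lifts[0] == pytest.approx(10.0)
        assert lifts[1:] == pytest.approx(0.0)

    def test_perfect_anti_ranking(self):
        labels = np.array([0] * 90 + [1] * 10)
        scores = np.linspace(1, 0, 100)
        assert lift_curve(scores, labels, n_bins=10)[0] == 0.0

    def test_random_scores_hover_at_one(self, rng):
        n = 10000
        labels = rng.integers(0, 2, size=n)
        lifts = lift_curve(rng.random(n), labels, n_bins=10)
        np.testing.assert_allclose(lifts, 1.0, atol=0.15)

    def test_more_bins_than_samples_rejected(self):
        with pytest.raises(ValueError):
            lift_curve(np.array([0.1, 0.9]), np.array([0, 1]), n_bins=3)


class TestJMDistance:
    def test_identical_distributions_give_zero(self, rng):
        X = rng.normal(size=(50, 4))
        assert jm_distance(X, X.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_unit_variance_mean_gap_closed_form(self):
        # sample mean 0 / 1 and sample variance exactly 1
        x0 = np.array([[-1.0], [0.0], [1.0]])
        x1 = x0 + 1.0
        expected = math.sqrt(2 * (1 - math.exp(-0.125)))
        assert jm_distance(x0, x1) == pytest.approx(expected, abs=1e-12)
        assert jm_distance(x0, x1) == pytest.approx(0.4848, abs=1e-4)

    def test_saturates_at_sqrt_two(self):
        x0 = np.array([[-1.0], [0.0], [1.0]])
        x1 = x0 + 1e6
        assert jm_distance(x0, x1) == pytest.approx(math.sqrt(2), abs=1e-9)

    def test_monotone_in_mean_separation(self):
        x0 = np.array([[-1.0], [0.0], [1.0]])
        gaps = [jm_distance(x0, x0 + d) for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(gaps, gaps[1:]))

    def test_bounded_on_random_data(self, rng):
        for _ in range(50):
            X0 = rng.normal(size=(20, 6))
            X1 = rng.normal(loc=rng.normal(), size=(20, 6))
            val = jm_distance(X0, X1)
            assert 0 <= val <= math.sqrt(2) + 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            jm_distance(np.zeros((1, 2)), np.zeros((5, 2)))

    def test_block_report(self, rng):
        X = rng.normal(size=(60, 6))
        y = np.repeat([0, 1], 30)
        X[y == 1, :3] += 2.0
        rep = jm_report(X, y, {"shifted": np.arange(3), "noise": np.arange(3, 6)})
        assert rep["shifted"] > rep["noise"]


class TestProtocols:
    def test_every_record_in_exactly_one_test_fold_per_run(self, small_sim):
        factory = default_pipeline_factory(k=16, net_config=FAST_NET)
        res = cross_validate(
            small_sim.manifest, small_sim.embeddings, factory, folds=3, runs=2, seed=0
        )
        for run in range(2):
            seen = [
                pid
                for fm in res.fold_metrics
                if fm["run"] == run
                for pid in fm["test_ids"]
            ]
            assert sorted(seen) == sorted(small_sim.manifest.ids)

    def test_aggregate_reports_mean_sd_ci(self, small_sim):
        factory = default_pipeline_factory(k=16, net_config=FAST_NET)
        res = cross_validate(
            small_sim.manifest, small_sim.embeddings, factory, folds=3, runs=1, seed=0
        )
        agg = res.aggregate()
        assert set(agg) == {
            "auc", "auprc", "precision", "recall", "accuracy", "specificity",
            "npv", "f1", "mcc", "kappa", "dor", "dp", "dkl",
        }
        assert agg["auc"]["ci95_low"] <= agg["auc"]["mean"] <= agg["auc"]["ci95_high"]

    def test_separable_dataset_scores_high(self, small_sim):
        factory = default_pipeline_factory(k=16, net_config=FAST_NET)
        res = cross_validate(
            small_sim.manifest, small_sim.embeddings, factory, folds=3, runs=1, seed=0
        )
        assert res.aggregate()["auc"]["mean"] >= 0.9

    def test_random_label_null_returns_requested_reps(self, small_sim):
        factory = default_pipeline_factory(k=16, net_config=FAST_NET)
        reports = random_label_null(
            small_sim.manifest, small_sim.embeddings, factory, reps=2, folds=3, seed=0
        )
        assert len(reports) == 2
        for rep in reports:
            assert abs(rep["prevalence"] - 0.5) < 0.2

    def test_independent_test_rejects_id_overlap(self, small_sim):
        factory = default_pipeline_factory(k=16, net_config=FAST_NET)
        records = list(small_sim.manifest)
        train = DatasetManifest(records=records[:100])
        test = DatasetManifest(records=records[90:])
        with pytest.raises(ValueError, match="overlap"):
            independent_test(train, test, small_sim.embeddings, factory)

    def test_test_labels_do_not_affect_scores(self, small_sim):
        from druggability import DruggabilityPipeline
        from druggability.records import ProteinRecord

        records = list(small_sim.manifest)
        pipe = DruggabilityPipeline(k=16, net_config=FAST_NET, random_state=0)
        pipe.fit(records[:100], small_sim.embeddings)
        test = records[100:]
        flipped = [
            ProteinRecord(id=r.id, sequence=r.sequence, go_terms=set(r.go_terms),
                          label=1 - r.label)
            for r in test
        ]
        a = pipe.predict_scores(test, small_sim.embeddings)
        b = pipe.predict_scores(flipped, small_sim.embeddings)
        np.testing.assert_array_equal(a, b)


def test_compute_all_metrics_names_and_count(rng):
    scores = rng.random(80)
    labels = rng.integers(0, 2, size=80)
    labels[:2] = [0, 1]
    out = compute_all_metrics(scores, labels)
    assert out["n"] == 80
    assert len([k for k in out if k != "n"]) == 13
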