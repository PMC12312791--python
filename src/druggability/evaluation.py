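"""Evaluation battery for binary druggability classifiers.

Thirteen metrics are reported per evaluation: AUC, AUPRC, precision,
recall, accuracy, specificity, NPV, F1, MCC, Cohen's kappa, diagnostic
odds ratio (DOR), discriminant power (DP = (sqrt(3)/pi) ln DOR) and a
Kullback–Leibler divergence (DKL) between the label prevalence and the
mean predicted score, both viewed as Bernoulli distributions (natural
log).  A Haldane–Anscombe +0.5 correction is applied to DOR/DP when any
confusion cell is zero; 0/0 rate metrics are reported as NaN rather than
coerced to 0.

The protocol pieces mirror the study design: stratified k-fold
cross-validation repeated over independent runs with every data-dependent
fit (GO vocabulary, standardizer, selection mask, network) nested inside
the training folds; a random-label binomial null at the observed
prevalence; a single-fit independent-test evaluation with a hard error on
id overlap; decile lift curves; and Jeffries–Matusita feature-block
separability under diagonal-covariance Gaussians, JM = sqrt(2(1 - e^-B))
with B the Bhattacharyya distance (range [0, sqrt(2)]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve, precision_recall_curve
from sklearn.model_selection import StratifiedKFold

from .pipeline import DruggabilityPipeline
from .records import DatasetManifest, ProteinRecord

METRIC_NAMES = (
    "auc",
    "auprc",
    "precision",
    "recall",
    "accuracy",
    "specificity",
    "npv",
    "f1",
    "mcc",
    "kappa",
    "dor",
    "dp",
    "dkl",
)


# ---------------------------------------------------------------------------
# Confusion counts and count-based metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int
    threshold: float = 0.5

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Count confusion cells; a score exactly at the threshold is positive."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary 0/1")
    calls = scores >= threshold
    return ConfusionCounts(
        TP=int(np.sum(calls & (labels == 1))),
        FP=int(np.sum(calls & (labels == 0))),
        TN=int(np.sum(~calls & (labels == 0))),
        FN=int(np.sum(~calls & (labels == 1))),
        threshold=threshold,
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Count-based metrics from a confusion table (closed forms)."""
    if c.n == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)
    n = tp + fp + tn + fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    npv = _ratio(tn, tn + fn)
    accuracy = (tp + tn) / n
    f1 = _ratio(2 * precision * recall, precision + recall) if not (
        math.isnan(precision) or math.isnan(recall)
    ) else float("nan")

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else float("nan")

    po = accuracy
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (po - pe) / (1 - pe) if pe != 1 else float("nan")

    # Haldane–Anscombe continuity correction only when a cell is zero
    if min(tp, fp, tn, fn) == 0:
        tp_, fp_, tn_, fn_ = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
    else:
        tp_, fp_, tn_, fn_ = tp, fp, tn, fn
    dor = (tp_ * tn_) / (fp_ * fn_)
    dp = (math.sqrt(3.0) / math.pi) * math.log(dor)

    return {
        "precision": precision,
        "recall": recall,
        "accuracy": accuracy,
        "specificity": specificity,
        "npv": npv,
        "f1": f1,
        "mcc": mcc,
        "kappa": kappa,
        "dor": dor,
        "dp": dp,
    }


# ---------------------------------------------------------------------------
# Ranking metrics, DKL, lift
# ---------------------------------------------------------------------------

def ranking_metrics(scores: np.ndarray, labels: np.ndarray) -> dict:
    """AUC (rank-based, ties half) and AUPRC (step-wise average precision)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for ranking metrics")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, prc_thr = precision_recall_curve(labels, scores)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "roc": (fpr, tpr, roc_thr),
        "prc": (prec, rec, prc_thr),
    }


def dkl(labels: np.ndarray, scores: np.ndarray) -> float:
    """KL(Bernoulli(prevalence) || Bernoulli(mean score)) in nats."""
    labels = np.asarray(labels, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.size < 1:
        raise ValueError("need at least one sample")
    lo, hi = 1e-12, 1 - 1e-12
    p = float(np.clip(labels.mean(), lo, hi))
    q = float(np.clip(scores.mean(), lo, hi))
    return p * math.log(p / q) + (1 - p) * math.log((1 - p) / (1 - q))


def lift_curve(
    scores: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Per-bin lift: precision within each score-sorted bin / prevalence.

    Samples are sorted by descending score (stable, so ties keep input
    order) and split into ``n_bins`` near-equal bins, top bin first.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if n_bins > scores.size:
        raise ValueError("n_bins cannot exceed the number of samples")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present for a lift curve")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    prevalence = labels.mean()
    return np.array(
        [chunk.mean() / prevalence for chunk in np.array_split(sorted_labels, n_bins)]
    )


def compute_all_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """The full 13-metric report for one evaluation."""
    out = classification_metrics(confusion(scores, labels, threshold))
    rank = ranking_metrics(scores, labels)
    out["auc"] = rank["auc"]
    out["auprc"] = rank["auprc"]
    out["dkl"] = dkl(labels, scores)
    out["n"] = int(np.asarray(labels).size)
    return out


# ---------------------------------------------------------------------------
# Cross-validation protocol
# ---------------------------------------------------------------------------

PipelineFactory = Callable[[int], DruggabilityPipeline]


def default_pipeline_factory(
    k: int = 4000, C: float = 1.0, net_config=None
) -> PipelineFactory:
    """A factory producing identically-configured pipelines per (run, fold)."""

    def make(random_state: int) -> DruggabilityPipeline:
        return DruggabilityPipeline(
            k=k, C=C, net_config=net_config, random_state=random_state
        )

    return make


@dataclass
class CVResult:
    """Per-fold metric grid with mean / SD / 95% CI aggregation."""

    fold_metrics: list[dict] = field(default_factory=list)  # run, fold, metrics
    folds: int = 10
    runs: int = 5

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([fm["metrics"][name] for fm in self.fold_metrics])

    def aggregate(self) -> dict[str, dict[str, float]]:
        """mean, sd and t-based 95% CI over all fold values, per metric."""
        out: dict[str, dict[str, float]] = {}
        for name in METRIC_NAMES:
            vals = self.metric_values(name)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            if vals.size > 1 and sd > 0:
                half = float(
                    stats.t.ppf(0.975, vals.size - 1) * sd / math.sqrt(vals.size)
                )
            else:
                half = 0.0
            out[name] = {
                "mean": mean,
                "sd": sd,
                "ci95_low": mean - half,
                "ci95_high": mean + half,
            }
        return out


def cross_validate(
    manifest: DatasetManifest | Sequence[ProteinRecord],
    embeddings: Mapping[str, np.ndarray],
    pipeline_factory: PipelineFactory,
    folds: int = 10,
    runs: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
    return_models: bool = False,
) -> CVResult:
    """Stratified k-fold CV repeated over independent runs.

    Every data-dependent object (GO vocabulary, standardizer, selection
    mask, network) is fitted inside :meth:`DruggabilityPipeline.fit` on the
    training folds only; the held-out fold is seen exclusively at scoring.
    """
    records = list(manifest)
    y = np.array([rec.label for rec in records])
    if any(rec.label is None for rec in records):
        raise ValueError("cross-validation requires labeled records")
    result = CVResult(folds=folds, runs=runs)
    for run in range(runs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=(seed + 1000 * run) % (2**31))
        for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(records)), y)):
            y_train = y[train_idx]
            if np.unique(y_train).size < 2:
                raise ValueError(f"run {run} fold {fold}: a class is absent from the training folds")
            fold_state = (seed + 1000 * run + fold) % (2**31)
            pipe = pipeline_factory(fold_state)
            train_records = [records[i] for i in train_idx]
            test_records = [records[i] for i in test_idx]
            pipe.fit(train_records, embeddings)
            scores = pipe.predict_scores(test_records, embeddings)
            metrics = compute_all_metrics(scores, y[test_idx], threshold)
            entry = {
                "run": run,
                "fold": fold,
                "metrics": metrics,
                "test_ids": [rec.id for rec in test_records],
            }
            if return_models:
                entry["model"] = pipe
            result.fold_metrics.append(entry)
    return result


def random_label_null(
    manifest: DatasetManifest,
    embeddings: Mapping[str, np.ndarray],
    pipeline_factory: PipelineFactory,
    reps: int = 5,
    folds: int = 10,
    runs: int = 1,
    seed: int = 0,
) -> list[dict]:
    """Random-classifier null: binomial relabeling at the observed prevalence.

    Each repetition independently relabels every protein Bernoulli(prevalence)
    and runs the full nested CV, so any selection-induced optimism would show
    up as AUC above chance.
    """
    records = list(manifest)
    y = np.array([rec.label for rec in records])
    prevalence = float(np.mean(y))
    rng = np.random.default_rng(seed)
    reports = []
    for rep in range(reps):
        labels = rng.binomial(1, prevalence, size=len(records))
        # degenerate single-class draws are redrawn (CV is undefined for them)
        while np.unique(labels).size < 2:
            labels = rng.binomial(1, prevalence, size=len(records))
        relabeled = [
            ProteinRecord(
                id=r.id, sequence=r.sequence, go_terms=set(r.go_terms), label=int(lab)
            )
            for r, lab in zip(records, labels)
        ]
        cv = cross_validate(
            relabeled,
            embeddings,
            pipeline_factory,
            folds=folds,
            runs=runs,
            seed=(seed + 7919 * (rep + 1)) % (2**31),
        )
        reports.append({"rep": rep, "prevalence": float(np.mean(labels)), "cv": cv})
    return reports


def independent_test(
    train_manifest: DatasetManifest,
    test_manifest: DatasetManifest,
    embeddings: Mapping[str, np.ndarray],
    pipeline_factory: PipelineFactory,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict[str, float]:
    """Single fit on all training data, single evaluation on the test set."""
    overlap = sorted(set(train_manifest.ids) & set(test_manifest.ids))
    if overlap:
        raise ValueError(f"train/test id overlap: {overlap[:10]}")
    pipe = pipeline_factory(seed % (2**31))
    pipe.fit(list(train_manifest), embeddings)
    scores = pipe.predict_scores(list(test_manifest), embeddings)
    return compute_all_metrics(scores, test_manifest.labels(), threshold)


# ---------------------------------------------------------------------------
# Jeffries–Matusita feature separability
# ---------------------------------------------------------------------------

def jm_distance(
    X_class0: np.ndarray, X_class1: np.ndarray, var_floor: float = 1e-6
) -> float:
    """JM = sqrt(2 (1 - e^-B)) between diagonal-covariance Gaussian fits.

    B = (1/8) (mu1-mu0)' S^-1 (mu1-mu0) + (1/2) ln(det S / sqrt(det S0 det S1))
    with S = (S0 + S1) / 2 and per-feature variances floored at ``var_floor``.
    The value lies in [0, sqrt(2)].
    """
    X0 = np.atleast_2d(np.asarray(X_class0, dtype=float))
    X1 = np.atleast_2d(np.asarray(X_class1, dtype=float))
    if X0.shape[0] < 2 or X1.shape[0] < 2:
        raise ValueError("need at least 2 samples per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    v0 = np.maximum(X0.var(axis=0, ddof=1), var_floor)
    v1 = np.maximum(X1.var(axis=0, ddof=1), var_floor)
    v_bar = (v0 + v1) / 2.0
    diff = mu1 - mu0
    b = 0.125 * np.sum(diff * diff / v_bar) + 0.5 * np.sum(
        np.log(v_bar) - 0.5 * (np.log(v0) + np.log(v1))
    )
    return float(math.sqrt(2.0 * (1.0 - math.exp(-b))))


def jm_report(
    X: np.ndarray, y: np.ndarray, blocks: Mapping[str, np.ndarray]
) -> dict[str, float]:
    """Per-feature-block JM distance between the two classes.

    ``blocks`` maps a category name (e.g. embedding block, a GO
    sub-ontology block) to the column indices of that block.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    out = {}
    for name, idx in blocks.items():
        idx = np.asarray(idx, dtype=int)
        out[name] = jm_distance(X[np.ix_(y == 0, idx)], X[np.ix_(y == 1, idx)])
    return out
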