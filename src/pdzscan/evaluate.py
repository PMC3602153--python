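"""Cross-validation schemes and performance metrics.

Four hold-out schemes estimate different generalization questions:

* ``tenfold`` — random partition of interactions into 10 sets;
* ``leave_domains`` — hold out 12% of domains with ALL their interactions
  (generalization to unseen domains), repeated ten times;
* ``leave_peptides`` — likewise with 8% of peptides;
* ``leave_both`` — both simultaneously;
* ``similarity_filtered`` — leave-domains with the additional constraint
  that every retained training domain has binding-site sequence
  similarity below a threshold to every test domain, with the training
  set capped at 500 interactions.

Metrics are sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP) (undefined ratios flagged as None, never reported as 0), plus
ROC AUC and PR AUC over the raw decision values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import svm as _svm

logger = logging.getLogger(__name__)

SCHEMES = ("tenfold", "leave_domains", "leave_peptides", "leave_both",
           "similarity_filtered")


class EvaluationError(ValueError):
    pass


@dataclass
class Metrics:
    sensitivity: float | None
    specificity: float | None
    precision: float | None


def compute_metrics(labels, predictions) -> Metrics:
    """Confusion-matrix ratios from true labels and +/-1 predictions."""
    labels = np.asarray(labels, int)
    predictions = np.asarray(predictions, int)
    if labels.shape != predictions.shape:
        raise EvaluationError("labels and predictions differ in length")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == -1)))
    tn = int(np.sum((labels == -1) & (predictions == -1)))
    fp = int(np.sum((labels == -1) & (predictions == 1)))

    def ratio(num, den):
        return num / den if den > 0 else None

    return Metrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        precision=ratio(tp, tp + fp),
    )


def roc_pr_auc(labels, decision_values) -> tuple[float, float]:
    """ROC AUC (trapezoidal; ties averaged) and PR AUC (step-wise)."""
    labels = np.asarray(labels, int)
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("ROC/PR AUC need both classes present")
    decision_values = np.asarray(decision_values, float)
    return (
        float(roc_auc_score(labels, decision_values)),
        float(average_precision_score(labels, decision_values)),
    )


def domain_similarity(seq_a: str, seq_b: str) -> float:
    """Fraction identity over the (equal-length) binding-site sequences."""
    if len(seq_a) != len(seq_b):
        raise EvaluationError("binding-site sequences differ in length")
    if not seq_a:
        raise EvaluationError("empty binding-site sequence")
    return sum(a == b for a, b in zip(seq_a, seq_b)) / len(seq_a)


@dataclass
class FoldResult:
    fold: int
    n_train: int
    n_test: int
    metrics: Metrics | None
    roc_auc: float | None
    pr_auc: float | None
    missing: bool = False
    labels: np.ndarray | None = None
    decision_values: np.ndarray | None = None
    test_indices: np.ndarray | None = None


@dataclass
class CVResult:
    scheme: str
    folds: list  # of FoldResult
    seed: int
    threshold: float | None = None
    params: dict = field(default_factory=dict)

    def _collect(self, attr):
        return [getattr(f, attr) for f in self.folds
                if not f.missing and getattr(f, attr) is not None]

    @property
    def mean_roc_auc(self) -> float:
        return float(np.mean(self._collect("roc_auc")))

    @property
    def mean_pr_auc(self) -> float:
        return float(np.mean(self._collect("pr_auc")))

    def pooled_auc(self) -> tuple[float, float]:
        """AUCs over decision values pooled across folds."""
        labels = np.concatenate([f.labels for f in self.folds if not f.missing])
        values = np.concatenate([f.decision_values for f in self.folds
                                 if not f.missing])
        return roc_pr_auc(labels, values)

    def to_rows(self):
        rows = []
        for f in self.folds:
            rows.append({
                "scheme": self.scheme,
                "threshold": self.threshold,
                "fold": f.fold,
                "n_train": f.n_train,
                "n_test": f.n_test,
                "roc_auc": f.roc_auc,
                "pr_auc": f.pr_auc,
                "sensitivity": f.metrics.sensitivity if f.metrics else None,
                "specificity": f.metrics.specificity if f.metrics else None,
                "precision": f.metrics.precision if f.metrics else None,
                "missing": f.missing,
            })
        return rows


def _evaluate_split(records, train_idx, test_idx, domain_vectors, fold_no,
                    gamma, c_negative, seed, max_train=None):
    train_recs = [records[i] for i in train_idx]
    test_recs = [records[i] for i in test_idx]
    if max_train is not None and len(train_recs) > max_train:
        # cap rng is independent of the fold stream so that a degenerate
        # threshold reproduces unfiltered fold composition exactly
        cap_rng = np.random.default_rng([seed, fold_no])
        keep = cap_rng.choice(len(train_recs), size=max_train, replace=False)
        train_recs = [train_recs[i] for i in sorted(keep)]
    train_labels = {r.label for r in train_recs}
    test_labels = {r.label for r in test_recs}
    if len(train_labels) < 2 or len(test_labels) < 2 or not train_recs:
        logger.warning("fold %d skipped: single-class or empty split", fold_no)
        return FoldResult(fold_no, len(train_recs), len(test_recs),
                          None, None, None, missing=True,
                          test_indices=np.asarray(test_idx, int))
    model = _svm.train(train_recs, domain_vectors, gamma=gamma,
                       c_negative=c_negative, seed=seed)
    preds = _svm.predict(model, [
        (r.domain_id, r.peptide, domain_vectors[r.domain_id]) for r in test_recs
    ])
    y = np.array([r.label for r in test_recs])
    decisions = np.array([p.decision_value for p in preds])
    hard = np.array([p.label for p in preds])
    roc, pr = roc_pr_auc(y, decisions)
    return FoldResult(fold_no, len(train_recs), len(test_recs),
                      compute_metrics(y, hard), roc, pr,
                      labels=y, decision_values=decisions,
                      test_indices=np.asarray(test_idx, int))


def _domain_holdout_split(records, rng, domain_frac=0.0, peptide_frac=0.0):
    """Indices for one repetition of an entity-holdout scheme."""
    test_mask = np.zeros(len(records), bool)
    if domain_frac > 0:
        domains = sorted({r.domain_id for r in records})
        n_hold = max(1, round(domain_frac * len(domains)))
        held = set(rng.choice(domains, size=n_hold, replace=False))
        test_mask |= np.array([r.domain_id in held for r in records])
    if peptide_frac > 0:
        peptides = sorted({r.peptide for r in records})
        n_hold = max(1, round(peptide_frac * len(peptides)))
        held = set(rng.choice(peptides, size=n_hold, replace=False))
        test_mask |= np.array([r.peptide in held for r in records])
    test_idx = np.flatnonzero(test_mask)
    train_idx = np.flatnonzero(~test_mask)
    return train_idx, test_idx


def run_cv(
    records,
    domain_vectors: dict,
    scheme: str = "tenfold",
    folds: int = 10,
    domain_frac: float = 0.12,
    peptide_frac: float = 0.08,
    repeats: int = 10,
    gamma: float = 0.01,
    c_negative: float = 1.0,
    seed: int = 0,
) -> CVResult:
    """Run one cross-validation scheme; scalers are refit per training fold
    (inside :func:`pdzscan.svm.train`), never on held-out data."""
    if scheme not in ("tenfold", "leave_domains", "leave_peptides", "leave_both"):
        raise EvaluationError(f"unknown scheme {scheme!r}")
    records = list(records)
    rng = np.random.default_rng(seed)
    results: list[FoldResult] = []
    if scheme == "tenfold":
        order = rng.permutation(len(records))
        parts = np.array_split(order, folds)
        for fold_no, test_idx in enumerate(parts):
            train_idx = np.setdiff1d(order, test_idx)
            results.append(_evaluate_split(
                records, train_idx, test_idx, domain_vectors, fold_no,
                gamma, c_negative, seed))
    else:
        dfrac = domain_frac if scheme in ("leave_domains", "leave_both") else 0.0
        pfrac = peptide_frac if scheme in ("leave_peptides", "leave_both") else 0.0
        for rep in range(repeats):
            train_idx, test_idx = _domain_holdout_split(records, rng, dfrac, pfrac)
            results.append(_evaluate_split(
                records, train_idx, test_idx, domain_vectors, rep,
                gamma, c_negative, seed))
    return CVResult(scheme=scheme, folds=results, seed=seed,
                    params={"folds": folds, "domain_frac": domain_frac,
                            "peptide_frac": peptide_frac, "repeats": repeats,
                            "gamma": gamma, "c_negative": c_negative})


def similarity_filtered_cv(
    records,
    domain_vectors: dict,
    site_sequences: dict,
    thresholds,
    folds: int = 10,
    repeats: int = 10,
    domain_frac: float = 0.12,
    max_train: int = 500,
    gamma: float = 0.01,
    c_negative: float = 1.0,
    seed: int = 0,
    similarity_fn=domain_similarity,
) -> dict:
    """Leave-domains CV with similarity-filtered training sets.

    Per run, 12% of domains are held out; a remaining domain is retained
    for training only if its binding-site sequence similarity to EVERY
    test domain is strictly below the threshold.  Training sets are capped
    at ``max_train`` interactions (random, seeded).  ``folds x repeats``
    runs per threshold; runs with an empty or single-class training set
    are recorded as missing, not zero.

    Returns {threshold: CVResult}.
    """
    records = list(records)
    out: dict[float, CVResult] = {}
    for threshold in thresholds:
        rng = np.random.default_rng(seed)  # same fold stream per threshold
        fold_results: list[FoldResult] = []
        run_no = 0
        for _rep in range(repeats):
            for _fold in range(folds):
                train_idx, test_idx = _domain_holdout_split(
                    records, rng, domain_frac=domain_frac)
                test_domains = {records[i].domain_id for i in test_idx}
                kept_domains = {
                    d for d in {records[i].domain_id for i in train_idx}
                    if all(similarity_fn(site_sequences[d], site_sequences[t])
                           < threshold for t in test_domains)
                }
                train_idx = np.array(
                    [i for i in train_idx if records[i].domain_id in kept_domains],
                    int)
                fold_results.append(_evaluate_split(
                    records, train_idx, test_idx, domain_vectors, run_no,
                    gamma, c_negative, seed, max_train=max_train))
                run_no += 1
        out[threshold] = CVResult(
            scheme="similarity_filtered", folds=fold_results, seed=seed,
            threshold=threshold,
            params={"folds": folds, "repeats": repeats, "max_train": max_train})
    return out


def cv_long_table(results) -> "object":
    """Long-format rows (threshold x AUC) ready for box plots; accepts a
    CVResult, an iterable of them, or the dict from similarity_filtered_cv."""
    import pandas as pd

    if hasattr(results, "values"):
        results = list(results.values())
    elif hasattr(results, "folds"):
        results = [results]
    rows = []
    for res in results:
        rows.extend(res.to_rows())
    return pd.DataFrame(rows)
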