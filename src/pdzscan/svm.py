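"""Cost-weighted RBF support-vector classifier over domain+peptide pairs.

The decision function is the standard soft-margin SVM dual expansion

    f(x) = sgn( sum_i alpha_i y_i K(x_i, x) + b ),    sgn(0) = +1

with RBF kernel K(x_i, x_j) = exp(-gamma ||x_i - x_j||^2) and per-class
box constraints: positives are penalized with C+ = (n+/n-) C- and
negatives with C-.  With n+ < n- this down-weights the positive class as
printed in the source protocol; ``invert_class_weights`` switches to the
conventional n-/n+ form.

The dual problem is solved by scikit-learn's SVC (libSVM); predictions are
evaluated here from the stored support vectors and dual coefficients, so
the kernel-expansion contract is the package's own code path.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .features import (
    FeatureScaler,
    N_PEPTIDE_FEATURES,
    N_STRUCTURE_FEATURES,
    PeptideFeatureVector,
    StructureFeatureVector,
    encode_peptide,
)

logger = logging.getLogger(__name__)

N_PAIR_FEATURES = N_STRUCTURE_FEATURES + N_PEPTIDE_FEATURES  # 340

DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))


class PredictorError(ValueError):
    pass


def assemble_pair_vector(domain_vec, pep_vec) -> np.ndarray:
    """Concatenate the 240 domain values and 100 peptide bits (340 total)."""
    dv = domain_vec.values if isinstance(domain_vec, StructureFeatureVector) \
        else np.asarray(domain_vec, float)
    pv = pep_vec.bits if isinstance(pep_vec, PeptideFeatureVector) \
        else np.asarray(pep_vec, float)
    if dv.shape != (N_STRUCTURE_FEATURES,) or pv.shape != (N_PEPTIDE_FEATURES,):
        raise PredictorError(
            f"expected {N_STRUCTURE_FEATURES}+{N_PEPTIDE_FEATURES} values, "
            f"got {dv.shape} + {pv.shape}"
        )
    return np.concatenate([dv, pv.astype(float)])


def rbf_kernel(x_i, x_j, gamma: float) -> float:
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    if x_i.shape != x_j.shape:
        raise PredictorError("kernel arguments must have equal length")
    if np.any(~np.isfinite(x_i)) or np.any(~np.isfinite(x_j)):
        raise PredictorError("NaN/inf in kernel input")
    if gamma < 0:
        raise PredictorError("gamma must be >= 0")
    return float(np.exp(-gamma * np.sum((x_i - x_j) ** 2)))


@dataclass
class Prediction:
    domain_id: str
    peptide: str
    decision_value: float
    label: int  # +1 iff decision_value >= 0

    def __post_init__(self):
        assert self.label == (1 if self.decision_value >= 0 else -1)


@dataclass
class TrainedModel:
    """Support vectors, dual coefficients alpha_i*y_i, bias, kernel and
    cost parameters, plus the feature scaler fitted on the training set."""

    support_vectors: np.ndarray  # (n_sv, 340)
    dual_coef: np.ndarray  # (n_sv,), alpha_i * y_i
    bias: float
    gamma: float
    c_positive: float
    c_negative: float
    scaler: FeatureScaler | None = None
    metadata: dict = field(default_factory=dict)

    def decision_value(self, x: np.ndarray) -> float:
        k = np.exp(-self.gamma * np.sum((self.support_vectors - x) ** 2, axis=1))
        return float(self.dual_coef @ k + self.bias)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        d2 = (
            np.sum(X ** 2, axis=1)[:, None]
            + np.sum(self.support_vectors ** 2, axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        return np.exp(-self.gamma * np.maximum(d2, 0.0)) @ self.dual_coef + self.bias

    def check_dual_constraints(self, tol: float = 1e-6) -> dict:
        """Verify the dual box constraints 0 <= alpha_i <= C(y_i) and the
        equality constraint sum_i alpha_i y_i = 0."""
        alphas = np.abs(self.dual_coef)
        cap = np.where(self.dual_coef > 0, self.c_positive, self.c_negative)
        return {
            "box_ok": bool(np.all(alphas <= cap + tol)),
            "max_box_violation": float(np.max(alphas - cap)),
            "sum_alpha_y": float(np.sum(self.dual_coef)),
        }

    # -- persistence (portable text archive) --------------------------------

    def to_text(self) -> str:
        fmt = lambda v: f"{float(v):.17g}"
        lines = [
            "# pdzscan svm model",
            f"gamma\t{fmt(self.gamma)}",
            f"c_positive\t{fmt(self.c_positive)}",
            f"c_negative\t{fmt(self.c_negative)}",
            f"bias\t{fmt(self.bias)}",
            f"n_sv\t{len(self.dual_coef)}",
        ]
        for key, value in sorted(self.metadata.items()):
            lines.append(f"meta:{key}\t{value}")
        if self.scaler is not None:
            lines.append("scaler_min\t" + "\t".join(fmt(v) for v in self.scaler.minimum))
            lines.append("scaler_max\t" + "\t".join(fmt(v) for v in self.scaler.maximum))
        for coef, sv in zip(self.dual_coef, self.support_vectors):
            lines.append(fmt(coef) + "\t" + "\t".join(fmt(v) for v in sv))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TrainedModel":
        header: dict[str, str] = {}
        meta: dict[str, str] = {}
        sv_rows: list[list[float]] = []
        coefs: list[float] = []
        scaler_min = scaler_max = None
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            key = parts[0]
            if key in ("gamma", "c_positive", "c_negative", "bias", "n_sv"):
                header[key] = parts[1]
            elif key.startswith("meta:"):
                meta[key[5:]] = parts[1]
            elif key == "scaler_min":
                scaler_min = np.array([float(v) for v in parts[1:]])
            elif key == "scaler_max":
                scaler_max = np.array([float(v) for v in parts[1:]])
            else:
                coefs.append(float(parts[0]))
                sv_rows.append([float(v) for v in parts[1:]])
        scaler = None
        if scaler_min is not None:
            scaler = FeatureScaler(minimum=scaler_min, maximum=scaler_max)
        return cls(
            support_vectors=np.array(sv_rows),
            dual_coef=np.array(coefs),
            bias=float(header["bias"]),
            gamma=float(header["gamma"]),
            c_positive=float(header["c_positive"]),
            c_negative=float(header["c_negative"]),
            scaler=scaler,
            metadata=meta,
        )


def build_design_matrix(records, domain_vectors: dict, scaler: FeatureScaler):
    """Stack scaled (domain, peptide) pair vectors for a record list."""
    X = np.empty((len(records), N_PAIR_FEATURES))
    y = np.empty(len(records), int)
    for i, rec in enumerate(records):
        dv = scaler.transform(np.asarray(domain_vectors[rec.domain_id], float))
        X[i] = assemble_pair_vector(dv, encode_peptide(rec.peptide))
        y[i] = rec.label
    return X, y


def train(
    records,
    domain_vectors: dict,
    gamma: float = 0.01,
    c_negative: float = 1.0,
    seed: int = 0,
    invert_class_weights: bool = False,
    tol: float = 1e-3,
) -> TrainedModel:
    """Fit the cost-weighted RBF SVM on interaction records.

    ``domain_vectors`` maps domain_id to the *unscaled* 240-vector; the
    min-max scaler is fitted here, on the training domains only, and is
    stored in the model for use at prediction time.
    """
    records = list(records)
    labels = {r.label for r in records}
    if labels != {+1, -1}:
        raise PredictorError(f"need both classes in training data, got {labels}")
    n_pos = sum(1 for r in records if r.label == +1)
    n_neg = len(records) - n_pos
    ratio = (n_neg / n_pos) if invert_class_weights else (n_pos / n_neg)
    c_positive = ratio * c_negative

    train_domains = {r.domain_id for r in records}
    scaler = FeatureScaler.fit(
        [np.asarray(domain_vectors[d], float) for d in sorted(train_domains)]
    )
    X, y = build_design_matrix(records, domain_vectors, scaler)
    svc = SVC(C=c_negative, kernel="rbf", gamma=gamma, tol=tol,
              class_weight={1: ratio, -1: 1.0}, random_state=seed)
    svc.fit(X, y)
    model = TrainedModel(
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        gamma=gamma,
        c_positive=c_positive,
        c_negative=c_negative,
        scaler=scaler,
        metadata={"n_pos": n_pos, "n_neg": n_neg, "seed": seed},
    )
    model._svc = svc  # kept for cross-checking; not persisted
    return model


def predict(model: TrainedModel, pairs) -> list[Prediction]:
    """Predict (domain_id, peptide, unscaled domain vector) triples.

    Domain vectors are transformed with the model's stored scaler; the
    decision value is the explicit kernel expansion over the model's
    support vectors, and the label is +1 iff the decision value is >= 0.
    """
    out: list[Prediction] = []
    X = np.empty((len(pairs), N_PAIR_FEATURES))
    ids = []
    for i, (domain_id, peptide, domain_vec) in enumerate(pairs):
        dv = np.asarray(domain_vec, float)
        if model.scaler is not None:
            dv = model.scaler.transform(dv)
        X[i] = assemble_pair_vector(dv, encode_peptide(peptide))
        ids.append((domain_id, peptide))
    # moderate extrapolation outside [0, 1] is legitimate for unseen
    # domains (no clamping); very large magnitudes suggest the caller
    # passed an already-scaled or otherwise wrong vector
    if len(pairs) and np.max(np.abs(X[:, :N_STRUCTURE_FEATURES])) > 20.0:
        logger.warning("scaled domain features have magnitude > 20; "
                       "was the input vector already scaled?")
    decisions = model.decision_values(X) if len(pairs) else np.empty(0)
    for (domain_id, peptide), decision in zip(ids, decisions):
        decision = float(decision)
        out.append(Prediction(domain_id, peptide, decision,
                              1 if decision >= 0 else -1))
    return out


def grid_search(
    records,
    domain_vectors: dict,
    gamma_grid=DEFAULT_GAMMA_GRID,
    c_grid=DEFAULT_C_GRID,
    inner_folds: int = 5,
    seed: int = 0,
    invert_class_weights: bool = False,
):
    """Pick (gamma, C-) maximizing mean inner-CV ROC AUC.

    Ties break toward smaller C, then smaller gamma.  Returns the winning
    point and the full score table [(gamma, c, mean_auc, n_folds_used)].
    Folds whose test half is single-class are skipped with a warning.
    """
    gamma_grid, c_grid = list(gamma_grid), list(c_grid)
    if not gamma_grid or not c_grid:
        raise PredictorError("empty grid")
    records = list(records)
    y_all = np.array([r.label for r in records])
    splitter = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = list(splitter.split(np.zeros(len(records)), y_all))

    table = []
    for gamma in gamma_grid:
        for c in c_grid:
            aucs = []
            for train_idx, test_idx in folds:
                train_recs = [records[i] for i in train_idx]
                test_recs = [records[i] for i in test_idx]
                test_y = np.array([r.label for r in test_recs])
                if len(set(test_y)) < 2 or len({r.label for r in train_recs}) < 2:
                    logger.warning("skipping degenerate single-class fold")
                    continue
                model = train(train_recs, domain_vectors, gamma=gamma,
                              c_negative=c, seed=seed,
                              invert_class_weights=invert_class_weights)
                preds = predict(model, [
                    (r.domain_id, r.peptide, domain_vectors[r.domain_id])
                    for r in test_recs
                ])
                aucs.append(roc_auc_score(
                    test_y, [p.decision_value for p in preds]))
            mean_auc = float(np.mean(aucs)) if aucs else float("nan")
            table.append((gamma, c, mean_auc, len(aucs)))
    best = max(
        (row for row in table if np.isfinite(row[2])),
        key=lambda row: (row[2], -row[1], -row[0]),
    )
    return (best[0], best[1]), table
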