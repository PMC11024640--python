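"""Trainable coding-potential classifiers and their two-model ensemble.

Two model kinds are supported, matching the algorithm families of the tools
whose feature schemas this package reimplements: an L2-penalized logistic
regression (CPAT-style) and an RBF-kernel soft-margin SVM whose decision
values are mapped to probabilities with a Platt sigmoid fitted on
out-of-fold decision values (LncFinder/PLEK-style). Features are z-scored
with training statistics; constant features are dropped and recorded.
Scores are calibrated probabilities that the transcript is a lncRNA
(the positive class), and a transcript is called lncRNA when its score is
greater than or equal to the model threshold.

The ensemble rule is intersection: a transcript is a lncRNA only when both
member models call it lncRNA. Disagreement resolves to mRNA — the stringent
choice, aimed at reducing false-positive lncRNA calls.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import ConfusionCounts, MetricSet, confusion, metrics, roc_curve
from .features import (
    CachedExtractor,
    FeatureVector,
    HexamerTable,
    extract_features,
    schema_feature_names,
)
from .features.hexamer import (
    N_HEXAMERS,
    build_hexamer_table,
    hexamer_indices,
)
from .features.orf import find_longest_orf
from .labels import LNCRNA, MRNA
from .seqio import NucleotideSequence

FORMAT_VERSION = "plantlnc-model-1"

MODEL_KINDS = ("logistic", "svm_rbf")
THRESHOLD_POLICIES = ("fixed_0.5", "youden_cv")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier kind, feature schema, and hyperparameters.

    ``l2`` is the L2 penalty strength for the logistic model (0 disables the
    penalty); ``C``/``gamma`` parameterize the SVM, with ``gamma="scale"``
    meaning the standard 1 / (n_features * var) heuristic.
    """

    kind: str
    schema_id: str
    l2: float = 1.0
    C: float = 1.0
    gamma: float | str = "scale"
    threshold_policy: str = "fixed_0.5"

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        schema_feature_names(self.schema_id)  # validates the schema id
        if self.l2 < 0:
            raise ValueError("l2 strength must be >= 0")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.threshold_policy not in THRESHOLD_POLICIES:
            raise ValueError(f"unknown threshold policy {self.threshold_policy!r}")


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix with binary labels: 1 = lncRNA (positive), 0 = mRNA."""

    ids: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    schema_id: str

    def __post_init__(self) -> None:
        if not (len(self.ids) == self.X.shape[0] == self.y.shape[0]):
            raise ValueError("ids, features and labels must have equal length")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature names must match matrix columns")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be 0/1")


def _sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z)))


@dataclass
class TrainedModel:
    """A fitted classifier bundled with everything needed to apply it."""

    spec: ModelSpec
    all_feature_names: tuple[str, ...]
    kept: np.ndarray  # boolean mask over all_feature_names
    mean: np.ndarray  # statistics of the kept features
    sd: np.ndarray
    params: dict
    threshold: float
    hexamer_table: HexamerTable | None = None
    dropped_features: tuple[str, ...] = field(default_factory=tuple)

    # -- scoring -----------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.mean) / self.sd

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        Z = self._standardize(X)
        if self.spec.kind == "logistic":
            return Z @ self.params["weights"] + self.params["intercept"]
        K = rbf_kernel(Z, self.params["support_vectors"], gamma=self.params["gamma"])
        return K @ self.params["dual_coef"] + self.params["intercept"]

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Lnc probability for each row of a full (pre-selection) feature matrix."""
        d = self.decision_values(X)
        if self.spec.kind == "logistic":
            return _sigmoid(d)
        return _sigmoid(self.params["platt_a"] * d + self.params["platt_b"])

    def _row(self, fv: FeatureVector) -> np.ndarray:
        if fv.schema_id != self.spec.schema_id:
            raise ValueError(
                f"feature schema {fv.schema_id!r} does not match model schema "
                f"{self.spec.schema_id!r}"
            )
        if fv.names[: len(self.all_feature_names)] != self.all_feature_names:
            lookup = fv.as_dict()
            try:
                return np.array([[lookup[n] for n in self.all_feature_names]])
            except KeyError as e:
                raise ValueError(f"feature vector is missing feature {e}") from e
        return fv.values[: len(self.all_feature_names)].reshape(1, -1)


def predict_score(model: TrainedModel, fv: FeatureVector) -> float:
    """Probability that the transcript is a lncRNA, in [0, 1]."""
    return float(model.score_matrix(model._row(fv))[0])


def classify(model: TrainedModel, fv: FeatureVector) -> str:
    """lncRNA iff the score reaches the model threshold (boundary counts in)."""
    return LNCRNA if predict_score(model, fv) >= model.threshold else MRNA


def extract_for_model(
    model: TrainedModel, seq: NucleotideSequence
) -> tuple[FeatureVector, float]:
    """Extract a sequence's features under the model's schema (using the
    model's own hexamer table) and score it."""
    fv = extract_features(seq, model.spec.schema_id, model.hexamer_table)
    return fv, predict_score(model, fv)


def ensemble_classify(
    model_a: TrainedModel,
    model_b: TrainedModel,
    fv_a: FeatureVector,
    fv_b: FeatureVector,
) -> str:
    """Intersection rule: lncRNA only when both members call lncRNA."""
    if classify(model_a, fv_a) == LNCRNA and classify(model_b, fv_b) == LNCRNA:
        return LNCRNA
    return MRNA


# -- training --------------------------------------------------------------


def _fit_logistic(Z: np.ndarray, y: np.ndarray, l2: float) -> dict:
    if l2 > 0:
        clf = LogisticRegression(C=1.0 / l2, solver="lbfgs", tol=1e-10, max_iter=20000)
    else:
        clf = LogisticRegression(penalty=None, solver="lbfgs", tol=1e-10, max_iter=20000)
    clf.fit(Z, y)
    return {"weights": clf.coef_[0].copy(), "intercept": float(clf.intercept_[0])}


def _fit_svm(Z: np.ndarray, y: np.ndarray, spec: ModelSpec, seed: int) -> dict:
    gamma = spec.gamma
    if gamma == "scale":
        v = Z.var()
        gamma = 1.0 / (Z.shape[1] * v) if v > 0 else 1.0 / Z.shape[1]
    svm = SVC(kernel="rbf", C=spec.C, gamma=gamma)
    # Platt calibration on out-of-fold decision values (3-fold, seeded)
    n_min = int(min(np.bincount(y.astype(int), minlength=2)))
    d_oof = np.empty(len(y))
    if n_min >= 3:
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(Z, y):
            fold_svm = SVC(kernel="rbf", C=spec.C, gamma=gamma)
            fold_svm.fit(Z[train_idx], y[train_idx])
            d_oof[test_idx] = fold_svm.decision_function(Z[test_idx])
    else:  # too few samples per class to fold; calibrate held-in
        svm.fit(Z, y)
        d_oof = svm.decision_function(Z)
    platt = LogisticRegression(C=1e10, solver="lbfgs", tol=1e-10, max_iter=20000)
    platt.fit(d_oof.reshape(-1, 1), y)
    svm.fit(Z, y)
    return {
        "support_vectors": svm.support_vectors_.copy(),
        "dual_coef": svm.dual_coef_[0].copy(),
        "intercept": float(svm.intercept_[0]),
        "gamma": float(gamma),
        "platt_a": float(platt.coef_[0, 0]),
        "platt_b": float(platt.intercept_[0]),
    }


def train_model(
    data: LabeledDataset,
    spec: ModelSpec,
    seed: int = 0,
    hexamer_table: HexamerTable | None = None,
) -> TrainedModel:
    """Fit a classifier on a labeled feature set.

    Raises on single-class data or non-finite features. ``hexamer_table`` is
    carried along inside the model so that prediction from raw sequences can
    re-extract features with the training-time table.
    """
    if data.schema_id != spec.schema_id:
        raise ValueError("dataset schema does not match model spec schema")
    if not np.all(np.isfinite(data.X)):
        raise ValueError("features contain non-finite values")
    if len(np.unique(data.y)) < 2:
        raise ValueError("training needs both classes present")
    mean_all = data.X.mean(axis=0)
    sd_all = data.X.std(axis=0)
    kept = sd_all > 0
    dropped = tuple(n for n, k in zip(data.feature_names, kept) if not k)
    Z = (data.X[:, kept] - mean_all[kept]) / sd_all[kept]
    y = data.y.astype(int)
    if spec.kind == "logistic":
        params = _fit_logistic(Z, y, spec.l2)
    else:
        params = _fit_svm(Z, y, spec, seed)
    model = TrainedModel(
        spec=spec,
        all_feature_names=tuple(data.feature_names),
        kept=kept,
        mean=mean_all[kept],
        sd=sd_all[kept],
        params=params,
        threshold=0.5,
        hexamer_table=hexamer_table,
        dropped_features=dropped,
    )
    if spec.threshold_policy == "youden_cv":
        model.threshold = _youden_threshold(model, data, spec, seed)
    return model


def _youden_threshold(
    model: TrainedModel, data: LabeledDataset, spec: ModelSpec, seed: int
) -> float:
    """Threshold maximizing Youden's J (TPR - FPR) on 3-fold out-of-fold scores."""
    y = data.y.astype(int)
    if int(min(np.bincount(y, minlength=2))) < 3:
        scores = model.score_matrix(data.X)
    else:
        scores = np.empty(len(y))
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for tr, te in skf.split(data.X, y):
            sub = LabeledDataset(
                tuple(data.ids[i] for i in tr),
                data.X[tr],
                data.y[tr],
                data.feature_names,
                data.schema_id,
            )
            fold_model = train_model(
                sub,
                ModelSpec(spec.kind, spec.schema_id, spec.l2, spec.C, spec.gamma),
                seed=seed,
            )
            scores[te] = fold_model.score_matrix(data.X[te])
    labels = [LNCRNA if v else MRNA for v in y]
    roc = roc_curve(scores, labels)
    j = roc.tpr - roc.fpr
    best = np.argmax(j)
    thr = roc.thresholds[best]
    if not np.isfinite(thr):
        thr = float(scores.max())
    return float(np.clip(thr, 1e-6, 1 - 1e-6))


# -- sequence-level helpers -------------------------------------------------


def build_dataset(
    pos: Sequence[NucleotideSequence],
    neg: Sequence[NucleotideSequence],
    schema_id: str,
    pseudocount: float = 1.0,
) -> tuple[LabeledDataset, HexamerTable]:
    """Feature dataset from labeled sequences (lncRNA positives, mRNA negatives).

    The hexamer background table is built from the same sequences: mRNAs as
    the coding background, lncRNAs as the noncoding background.
    """
    table = build_hexamer_table(coding=list(neg), noncoding=list(pos), pseudocount=pseudocount)
    seqs = list(pos) + list(neg)
    ex = CachedExtractor(seqs, schema_id)
    X = ex.matrix(table) if schema_id != "plek" else ex.matrix()
    y = np.array([1] * len(pos) + [0] * len(neg))
    return (
        LabeledDataset(tuple(s.id for s in seqs), X, y, ex.names, schema_id),
        table,
    )


def train_from_sequences(
    pos: Sequence[NucleotideSequence],
    neg: Sequence[NucleotideSequence],
    spec: ModelSpec,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> TrainedModel:
    data, table = build_dataset(pos, neg, spec.schema_id, pseudocount)
    return train_model(data, spec, seed=seed, hexamer_table=table)


@dataclass(frozen=True)
class CrossValResult:
    fold_metrics: list[MetricSet]
    pooled_metrics: MetricSet
    pooled_confusion: ConfusionCounts
    oof_scores: np.ndarray
    true_labels: tuple[str, ...]


def cross_validate(
    pos: Sequence[NucleotideSequence],
    neg: Sequence[NucleotideSequence],
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> CrossValResult:
    """Stratified k-fold cross-validation from raw labeled sequences.

    Hexamer background tables and feature standardization are rebuilt from
    each fold's training partition only, so no test-fold information leaks
    into the features or the fit. Returns per-fold metrics, the pooled
    confusion over all folds, and the out-of-fold scores (for ROC/AUC).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pos) < k or len(neg) < k:
        raise ValueError("each class needs at least k samples")
    seqs = list(pos) + list(neg)
    y = np.array([1] * len(pos) + [0] * len(neg))
    needs_table = spec.schema_id != "plek"
    ex = CachedExtractor(seqs, spec.schema_id)
    # per-sequence hexamer index lists so fold tables are cheap count sums
    if needs_table:
        cod_idx, non_idx = [], []
        for s in seqs:
            orf = find_longest_orf(s, require_stop=False)
            cod_idx.append(
                hexamer_indices(s.residues, 3, orf.start, orf.end)
                if orf.length_nt >= 6
                else np.empty(0, dtype=np.int64)
            )
            non_idx.append(hexamer_indices(s.residues, 1))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_metrics: list[MetricSet] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    oof = np.empty(len(seqs))
    true_labels = tuple(LNCRNA if v else MRNA for v in y)
    for tr, te in skf.split(np.zeros(len(seqs)), y):
        table = None
        if needs_table:
            cod_counts = np.zeros(N_HEXAMERS)
            non_counts = np.zeros(N_HEXAMERS)
            n_cod = n_non = 0
            for i in tr:
                if y[i] == 0:
                    cod_counts += np.bincount(cod_idx[i], minlength=N_HEXAMERS)
                    n_cod += cod_idx[i].size
                else:
                    non_counts += np.bincount(non_idx[i], minlength=N_HEXAMERS)
                    n_non += non_idx[i].size
            sc, sn = cod_counts + pseudocount, non_counts + pseudocount
            table = HexamerTable(
                np.log(sc / sc.sum()), np.log(sn / sn.sum()), pseudocount, n_cod, n_non
            )
        X = ex.matrix(table) if needs_table else ex.matrix()
        sub = LabeledDataset(
            tuple(seqs[i].id for i in tr), X[tr], y[tr], ex.names, spec.schema_id
        )
        model = train_model(sub, spec, seed=seed, hexamer_table=table)
        scores = model.score_matrix(X[te])
        oof[te] = scores
        pred = [LNCRNA if s >= model.threshold else MRNA for s in scores]
        truth = [true_labels[i] for i in te]
        cc = confusion(truth, pred)
        fold_metrics.append(metrics(cc))
        pooled = pooled + cc
    return CrossValResult(fold_metrics, metrics(pooled), pooled, oof, true_labels)


# -- serialization ----------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model (spec, scaling, parameters, table, threshold)
    to a single JSON file."""
    params = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in model.params.items()
    }
    doc = {
        "format_version": FORMAT_VERSION,
        "spec": {
            "kind": model.spec.kind,
            "schema_id": model.spec.schema_id,
            "l2": model.spec.l2,
            "C": model.spec.C,
            "gamma": model.spec.gamma,
            "threshold_policy": model.spec.threshold_policy,
        },
        "all_feature_names": list(model.all_feature_names),
        "kept": model.kept.tolist(),
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "params": params,
        "threshold": model.threshold,
        "dropped_features": list(model.dropped_features),
        "hexamer_table": None
        if model.hexamer_table is None
        else {
            "coding_logfreq": model.hexamer_table.coding_logfreq.tolist(),
            "noncoding_logfreq": model.hexamer_table.noncoding_logfreq.tolist(),
            "pseudocount": model.hexamer_table.pseudocount,
            "n_coding_hexamers": model.hexamer_table.n_coding_hexamers,
            "n_noncoding_hexamers": model.hexamer_table.n_noncoding_hexamers,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def load_model(path: str | Path) -> TrainedModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported model format {doc.get('format_version')!r}")
    spec = ModelSpec(**doc["spec"])
    params = {
        k: (np.array(v) if isinstance(v, list) else v) for k, v in doc["params"].items()
    }
    table = None
    if doc["hexamer_table"] is not None:
        t = doc["hexamer_table"]
        table = HexamerTable(
            np.array(t["coding_logfreq"]),
            np.array(t["noncoding_logfreq"]),
            t["pseudocount"],
            t["n_coding_hexamers"],
            t["n_noncoding_hexamers"],
        )
    return TrainedModel(
        spec=spec,
        all_feature_names=tuple(doc["all_feature_names"]),
        kept=np.array(doc["kept"], dtype=bool),
        mean=np.array(doc["mean"]),
        sd=np.array(doc["sd"]),
        params=params,
        threshold=doc["threshold"],
        hexamer_table=table,
        dropped_features=tuple(doc["dropped_features"]),
    )
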