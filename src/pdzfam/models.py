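"""Per-family RBF-kernel SVM models with nested cross-validated evaluation.

Each specificity family with enough data gets its own Gaussian-kernel SVM
over the binary peptide encoding (optionally extended with structure
contact-pair features). Families need at least 10 experimentally measured
positives to be modelled at all, and at least 10 experimental positives and
10 experimental negatives to enter cross-validation, so that every test
fold holds at least 2 of each. Evaluation is 5-fold stratified CV with the
hyperparameters (C, gamma) chosen per outer fold by an inner 5-fold grid
search on the training portion only; generated (ssl/random) negatives are
regenerated inside each training portion and never reach a test fold.
Decision scores above 0 call a binder; a Platt sigmoid fitted on
out-of-fold decision scores supplies calibrated probabilities.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import negatives as neg_mod
from .encoding import ContactMap, encode_combined, encode_sequence
from .records import InteractionRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRID",
    "FamilyEncoder",
    "TrainedFamilyModel",
    "MetricsEntry",
    "FoldResult",
    "EvaluationReport",
    "eligible_for_modeling",
    "eligible_for_cv",
    "stratified_kfold",
    "grid_search",
    "train_family_model",
    "compute_metrics",
    "cross_validate",
]

MIN_POSITIVES_MODEL = 10
MIN_POSITIVES_CV = 10
MIN_NEGATIVES_CV = 10

#: Default hyperparameter grid: C and gamma in powers of 4 over the
#: standard RBF ranges 2^-5..2^15 and 2^-15..2^3.
DEFAULT_GRID: tuple[tuple[float, float], ...] = tuple(
    (2.0**c, 2.0**g)
    for c in range(-5, 16, 2)
    for g in range(-15, 4, 2)
)

#: Small grid for quick fits and tests; covers the useful corner of the
#: default grid at a fraction of the cost.
SMALL_GRID: tuple[tuple[float, float], ...] = tuple(
    (2.0**c, 2.0**g) for c in (0, 4) for g in (-7, -3)
)


def _experimental_counts(records: Sequence[InteractionRecord]) -> tuple[int, int]:
    pos = sum(1 for r in records if r.provenance == "experimental" and r.label == 1)
    neg = sum(1 for r in records if r.provenance == "experimental" and r.label == -1)
    return pos, neg


def eligible_for_modeling(records: Sequence[InteractionRecord]) -> bool:
    """A family is modelable iff it has >= 10 experimental positives."""
    pos, _ = _experimental_counts(records)
    return pos >= MIN_POSITIVES_MODEL


def eligible_for_cv(records: Sequence[InteractionRecord]) -> bool:
    """CV needs >= 10 experimental positives and >= 10 experimental negatives."""
    pos, neg = _experimental_counts(records)
    return pos >= MIN_POSITIVES_CV and neg >= MIN_NEGATIVES_CV


def stratified_kfold(
    records: Sequence[InteractionRecord], k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split of interaction records.

    Returns (train_indices, test_indices) per fold; per-class counts differ
    by at most 1 across folds. Raises if either class has fewer than k
    records.
    """
    y = np.array([r.label for r in records])
    for cls in (-1, 1):
        if (y == cls).sum() < k:
            raise ValueError(
                f"class {cls:+d} has {(y == cls).sum()} records; need >= {k} for "
                f"{k}-fold stratification"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]


@dataclass
class FamilyEncoder:
    """Maps (domain id, peptide) to the family's feature vector.

    ``mode="sequence"`` ignores the domain and emits the 100-bit one-hot
    peptide encoding. ``mode="combined"`` appends 400-bit contact-pair
    blocks and therefore needs the family contact map (in MSA coordinates)
    plus each member domain's gapped MSA row.
    """

    mode: str = "sequence"
    contacts: Optional[ContactMap] = None
    aligned_sequences: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        if self.mode not in ("sequence", "combined"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")
        if self.mode == "combined":
            if self.contacts is None or len(self.contacts) < 1:
                raise ValueError("combined mode needs a non-empty contact map")
            if not self.aligned_sequences:
                raise ValueError("combined mode needs aligned domain sequences")

    @property
    def dim(self) -> int:
        if self.mode == "sequence":
            return 100
        return 100 + 400 * len(self.contacts)

    def encode(self, peptide, domain_id: Optional[str] = None) -> np.ndarray:
        if self.mode == "sequence":
            return encode_sequence(peptide)
        if domain_id is None or domain_id not in self.aligned_sequences:
            raise ValueError(f"no aligned sequence for domain {domain_id!r}")
        return encode_combined(self.aligned_sequences[domain_id], peptide, self.contacts)

    def encode_records(
        self, records: Sequence[InteractionRecord]
    ) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([self.encode(r.peptide, r.domain_id) for r in records])
        y = np.array([r.label for r in records])
        return X, y


class _PlattCalibrator:
    """Sigmoid map from decision score to positive-class probability.

    Fitted on out-of-fold decision scores (Platt scaling via an
    unregularised 1-D logistic fit); monotone non-decreasing by
    construction when the positive class scores higher.
    """

    def __init__(self) -> None:
        self._lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)

    def fit(self, scores: np.ndarray, labels: np.ndarray) -> "_PlattCalibrator":
        self._lr.fit(scores.reshape(-1, 1), labels)
        return self

    def probability(self, scores: np.ndarray) -> np.ndarray:
        proba = self._lr.predict_proba(np.asarray(scores).reshape(-1, 1))
        pos_col = list(self._lr.classes_).index(1)
        return proba[:, pos_col]


def _manifest_entry(r: InteractionRecord) -> dict:
    return {
        "domain_id": r.domain_id,
        "peptide": str(r.peptide),
        "label": r.label,
        "provenance": r.provenance,
    }


@dataclass
class TrainedFamilyModel:
    """A fitted family classifier plus everything needed to reuse it."""

    family_id: str
    encoding_mode: str
    C: float
    gamma: float
    svm: SVC
    calibrator: _PlattCalibrator
    encoder: FamilyEncoder
    manifest: list[dict] = field(default_factory=list)

    def decision_score(
        self, peptides: Sequence, domain_id: Optional[str] = None
    ) -> np.ndarray:
        X = np.array([self.encoder.encode(p, domain_id) for p in peptides])
        return self.svm.decision_function(X)

    def probability(
        self, peptides: Sequence, domain_id: Optional[str] = None
    ) -> np.ndarray:
        return self.calibrator.probability(self.decision_score(peptides, domain_id))

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        joblib.dump(self, path / "model.joblib")
        summary = {
            "family_id": self.family_id,
            "encoding_mode": self.encoding_mode,
            "C": self.C,
            "gamma": self.gamma,
            "n_training_records": len(self.manifest),
            "training_manifest": self.manifest,
        }
        (path / "manifest.json").write_text(json.dumps(summary, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedFamilyModel":
        return joblib.load(Path(path) / "model.joblib")


def grid_search(
    records: Sequence[InteractionRecord],
    encoder: Optional[FamilyEncoder] = None,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Exhaustive (C, gamma) search maximising inner-CV mean AUC-ROC.

    Ties are broken toward the smallest C, then the smallest gamma. If a
    class is too small for k inner folds the fold count is shrunk (with a
    warning) down to 2; below that the search fails.
    """
    encoder = encoder or FamilyEncoder()
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    if len(grid) == 1:
        return grid[0]
    X, y = encoder.encode_records(records)
    n_min = min(int((y == 1).sum()), int((y == -1).sum()))
    if n_min < 2:
        raise ValueError("grid search needs >= 2 records of each class")
    k_eff = min(k, n_min)
    if k_eff < k:
        warnings.warn(
            f"grid search: shrinking inner folds from {k} to {k_eff}",
            RuntimeWarning,
            stacklevel=2,
        )
    splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    folds = list(splitter.split(X, y))
    best: Optional[tuple[float, float, float]] = None  # (auc, C, gamma)
    for C, gamma in grid:
        aucs = []
        for tr, te in folds:
            clf = SVC(kernel="rbf", C=C, gamma=gamma)
            clf.fit(X[tr], y[tr])
            scores = clf.decision_function(X[te])
            if len(set(y[te])) < 2:
                continue
            aucs.append(roc_auc_score(y[te], scores))
        mean_auc = float(np.mean(aucs)) if aucs else 0.5
        if (
            best is None
            or mean_auc > best[0] + 1e-12
            or (abs(mean_auc - best[0]) <= 1e-12 and (C, gamma) < (best[1], best[2]))
        ):
            best = (mean_auc, C, gamma)
    return best[1], best[2]


def train_family_model(
    family_id: str,
    records: Sequence[InteractionRecord],
    hyperparams: tuple[float, float],
    encoder: Optional[FamilyEncoder] = None,
    calibration_folds: int = 5,
    seed: int = 0,
) -> TrainedFamilyModel:
    """Fit the family SVM and its probability calibration.

    The SVM is fitted on all given records; the Platt sigmoid is fitted on
    out-of-fold decision scores from a stratified split of the same records
    (held-out predictions), falling back to in-sample scores when a class is
    too small to split.
    """
    encoder = encoder or FamilyEncoder()
    C, gamma = hyperparams
    X, y = encoder.encode_records(records)
    if len(set(y)) < 2:
        raise ValueError("training needs both classes")
    svm = SVC(kernel="rbf", C=C, gamma=gamma)
    svm.fit(X, y)

    n_min = min(int((y == 1).sum()), int((y == -1).sum()))
    cal_scores = np.empty(len(y))
    if n_min >= 2:
        k_eff = max(2, min(calibration_folds, n_min))
        splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
        for tr, te in splitter.split(X, y):
            fold_svm = SVC(kernel="rbf", C=C, gamma=gamma)
            fold_svm.fit(X[tr], y[tr])
            cal_scores[te] = fold_svm.decision_function(X[te])
    else:
        cal_scores = svm.decision_function(X)
    calibrator = _PlattCalibrator().fit(cal_scores, y)
    return TrainedFamilyModel(
        family_id=family_id,
        encoding_mode=encoder.mode,
        C=C,
        gamma=gamma,
        svm=svm,
        calibrator=calibrator,
        encoder=encoder,
        manifest=[_manifest_entry(r) for r in records],
    )


@dataclass
class MetricsEntry:
    """Confusion counts and threshold-free measures for one score set."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    auc_roc: float
    auc_pr: float


def compute_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.0
) -> MetricsEntry:
    """Sensitivity/specificity/precision at a score threshold, plus AUCs.

    A score strictly above ``threshold`` calls a binder. AUC-ROC uses the
    trapezoidal sweep (equivalently Mann-Whitney with half credit for
    ties); AUC-PR integrates the interpolated precision-recall sweep.
    Precision with no positive calls is reported as 0. Both classes must be
    present for the AUCs to be defined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if set(labels) != {-1, 1}:
        raise ValueError("AUCs undefined: need both classes in labels")
    calls = scores > threshold
    pos = labels == 1
    tp = int((calls & pos).sum())
    fp = int((calls & ~pos).sum())
    fn = int((~calls & pos).sum())
    tn = int((~calls & ~pos).sum())
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    auc_roc = float(roc_auc_score(labels, scores))
    prec_curve, rec_curve, _ = precision_recall_curve(labels, scores)
    # precision_recall_curve returns recall decreasing; integrate over recall.
    auc_pr = float(-np.trapezoid(prec_curve, rec_curve))
    return MetricsEntry(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        auc_roc=auc_roc,
        auc_pr=auc_pr,
    )


@dataclass
class FoldResult:
    fold: int
    C: float
    gamma: float
    metrics: MetricsEntry
    train_manifest: list[dict]
    test_manifest: list[dict]


@dataclass
class EvaluationReport:
    """Per-fold results and their means for one family."""

    family_id: str
    folds: list[FoldResult]

    def mean(self, attr: str) -> float:
        return float(np.mean([getattr(f.metrics, attr) for f in self.folds]))

    def summary(self) -> dict[str, float]:
        return {
            a: self.mean(a)
            for a in ("sensitivity", "specificity", "precision", "auc_roc", "auc_pr")
        }


def cross_validate(
    family_id: str,
    records: Sequence[InteractionRecord],
    k: int = 5,
    seed: int = 0,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    encoder: Optional[FamilyEncoder] = None,
    pool: Optional["neg_mod.UnlabeledPool"] = None,
    ratio: int = neg_mod.DEFAULT_RATIO,
    window: tuple[float, float] = neg_mod.DEFAULT_WINDOW,
) -> EvaluationReport:
    """Nested stratified cross-validation of a family model.

    Only experimental records are folded (test sets contain exclusively
    experimentally verified interactions). Within each fold, generated
    negatives are produced afresh from the training portion: self-training
    when the training portion has both classes and a pool is supplied,
    uniform random draws otherwise. The grid search sees only the fold's
    training data (nested selection); metrics are computed on the held-out
    experimental records with the binder threshold at score 0.
    """
    experimental = [r for r in records if r.provenance == "experimental"]
    if not eligible_for_cv(experimental):
        pos, neg = _experimental_counts(experimental)
        raise ValueError(
            f"family {family_id} not CV-eligible: {pos} experimental positives, "
            f"{neg} experimental negatives (need >= 10 of each)"
        )
    encoder = encoder or FamilyEncoder()
    folds = stratified_kfold(experimental, k=k, seed=seed)
    results: list[FoldResult] = []
    for fold_no, (tr, te) in enumerate(folds, start=1):
        train = [experimental[i] for i in tr]
        test = [experimental[i] for i in te]
        if pool is not None:
            test_peptides = {str(r.peptide) for r in test}
            fold_pool = pool.without(test_peptides)
            n_neg = sum(1 for r in train if r.label == -1)
            if n_neg > 0:
                ssl = neg_mod.self_train_negatives(
                    train, fold_pool, window=window, ratio=ratio, seed=seed + fold_no
                )
                train = ssl.records
            else:
                train = list(train) + neg_mod.random_negatives(
                    [r for r in train if r.label == 1],
                    fold_pool,
                    ratio=ratio,
                    seed=seed + fold_no,
                )
        C, gamma = grid_search(train, encoder=encoder, grid=grid, k=k, seed=seed)
        model = train_family_model(
            family_id, train, (C, gamma), encoder=encoder, seed=seed
        )
        scores = np.array(
            [model.decision_score([r.peptide], r.domain_id)[0] for r in test]
        )
        labels = np.array([r.label for r in test])
        metrics = compute_metrics(scores, labels)
        results.append(
            FoldResult(
                fold=fold_no,
                C=C,
                gamma=gamma,
                metrics=metrics,
                train_manifest=[_manifest_entry(r) for r in train],
                test_manifest=[_manifest_entry(r) for r in test],
            )
        )
    return EvaluationReport(family_id=family_id, folds=results)
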