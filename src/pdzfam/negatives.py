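"""Negative-class enrichment for family interaction sets.

High-throughput domain-peptide screens give almost exclusively positive
interactions, so the negative class is enriched in two ways. Families with
measured negatives get semi-supervised self-training: a base classifier
(RBF SVM with Platt-calibrated probabilities over the one-hot peptide
encoding) is trained on the labeled data, scores the unlabeled C-terminal
peptides of the relevant proteome, and candidates whose negative-class
probability falls in a confidence window (default [0.5, 0.8]; higher-scoring
peptides are deliberately excluded as too far from the positive class) are
sampled into the training set as negatives until negatives outnumber
positives 5:1. Families with only positive data instead draw negatives
uniformly at random from the same proteome pool. Generated negatives are
flagged by provenance (``ssl`` / ``random``) and must never enter test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .alphabet import AA20
from .encoding import encode_sequence
from .records import InteractionRecord, Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "UnlabeledPool",
    "PeptideClassifier",
    "SelfTrainingResult",
    "extract_cterm_peptides",
    "self_train_negatives",
    "random_negatives",
]

DEFAULT_WINDOW = (0.5, 0.8)
DEFAULT_RATIO = 5


@dataclass(frozen=True)
class UnlabeledPool:
    """Deduplicated C-terminal 5-mers of a proteome."""

    peptides: frozenset[str]
    organism: str = "synthetic"
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.peptides)

    def without(self, exclude: Iterable[str]) -> "UnlabeledPool":
        """The pool minus a set of peptides (e.g. a family's labeled data)."""
        excl = {str(p) for p in exclude}
        return UnlabeledPool(
            peptides=frozenset(p for p in self.peptides if p not in excl),
            organism=self.organism,
            n_skipped=self.n_skipped,
        )


def extract_cterm_peptides(
    proteome: dict[str, str], organism: str = "synthetic"
) -> UnlabeledPool:
    """Last-5-residue peptides of every protein, deduplicated.

    Proteins shorter than 5 residues, or with a non-standard residue among
    their last 5 positions, are skipped (counted in ``n_skipped``).
    """
    if not proteome:
        raise ValueError("empty proteome")
    peptides: set[str] = set()
    skipped = 0
    valid = set(AA20)
    for pid, seq in proteome.items():
        seq = seq.upper()
        if len(seq) < 5:
            skipped += 1
            continue
        tail = seq[-5:]
        if set(tail) - valid:
            skipped += 1
            continue
        peptides.add(tail)
    if skipped:
        logger.info("extract_cterm_peptides: skipped %d proteins", skipped)
    return UnlabeledPool(frozenset(peptides), organism=organism, n_skipped=skipped)


class PeptideClassifier:
    """RBF-SVM over the one-hot peptide encoding with calibrated probabilities.

    The Platt sigmoid calibration is fitted on held-out folds
    (CalibratedClassifierCV), so ``negative_probability`` returns a genuine
    probability of the negative class for any 5-mer.
    """

    def __init__(self, C: float = 1.0, gamma: float | str = "scale", cv: int = 5):
        self.C = C
        self.gamma = gamma
        self.cv = cv
        self._model: Optional[CalibratedClassifierCV] = None

    def fit(self, records: Sequence[InteractionRecord]) -> "PeptideClassifier":
        X = np.array([encode_sequence(r.peptide) for r in records])
        y = np.array([r.label for r in records])
        n_min = min(int((y == 1).sum()), int((y == -1).sum()))
        if n_min == 0:
            raise ValueError("base classifier needs both classes")
        cv = max(2, min(self.cv, n_min))
        base = SVC(kernel="rbf", C=self.C, gamma=self.gamma)
        self._model = CalibratedClassifierCV(base, method="sigmoid", cv=cv)
        self._model.fit(X, y)
        return self

    def negative_probability(self, peptides: Sequence[str | Peptide]) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("classifier not fitted")
        X = np.array([encode_sequence(str(p)) for p in peptides])
        proba = self._model.predict_proba(X)
        neg_col = list(self._model.classes_).index(-1)
        return proba[:, neg_col]


@dataclass
class SelfTrainingResult:
    """Augmented training set plus the classifiers from both passes."""

    records: list[InteractionRecord]
    base_classifier: PeptideClassifier
    final_classifier: PeptideClassifier
    n_candidates: int
    exhausted: bool = False


def self_train_negatives(
    labeled: Sequence[InteractionRecord],
    pool: UnlabeledPool,
    window: tuple[float, float] = DEFAULT_WINDOW,
    ratio: int = DEFAULT_RATIO,
    seed: int = 0,
    base_params: Optional[dict] = None,
) -> SelfTrainingResult:
    """One self-training round enriching the negative class.

    Train the base classifier on the labeled records, score the unlabeled
    pool, keep candidates whose negative-class probability lies in
    ``window`` (inclusive endpoints; candidates above the upper bound are
    excluded as over-confident), and sample uniformly without replacement
    until total negatives reach ``ratio`` times the positives, or the
    candidates run out. Sampled peptides are appended with label -1 and
    provenance ``ssl``; the classifier is retrained on the augmented set.
    """
    labels = {r.label for r in labeled}
    if labels != {-1, 1}:
        raise ValueError(
            "self-training needs both positively and negatively labeled data"
        )
    labeled_peptides = {str(r.peptide) for r in labeled}
    pool = pool.without(labeled_peptides)
    base = PeptideClassifier(**(base_params or {})).fit(labeled)
    if len(pool) == 0:
        logger.warning("self_train_negatives: empty pool; returning labeled set")
        return SelfTrainingResult(list(labeled), base, base, 0, exhausted=True)

    candidates = sorted(pool.peptides)  # stable order before seeding
    probs = base.negative_probability(candidates)
    lo, hi = window
    in_window = [p for p, q in zip(candidates, probs) if lo <= q <= hi]

    n_pos = sum(1 for r in labeled if r.label == 1)
    n_neg = sum(1 for r in labeled if r.label == -1)
    quota = max(0, ratio * n_pos - n_neg)
    rng = np.random.default_rng(seed)
    take = min(quota, len(in_window))
    chosen = sorted(rng.choice(len(in_window), size=take, replace=False)) if take else []
    exhausted = len(in_window) < quota
    if exhausted:
        logger.warning(
            "self_train_negatives: only %d window candidates for quota %d",
            len(in_window),
            quota,
        )
    # Example domain id: SSL negatives apply family-wide; reuse the first record's.
    domain_id = labeled[0].domain_id
    ssl_records = [
        InteractionRecord(
            domain_id=domain_id,
            peptide=Peptide(in_window[i]),
            label=-1,
            provenance="ssl",
        )
        for i in chosen
    ]
    augmented = list(labeled) + ssl_records
    final = PeptideClassifier(**(base_params or {})).fit(augmented)
    return SelfTrainingResult(
        records=augmented,
        base_classifier=base,
        final_classifier=final,
        n_candidates=len(in_window),
        exhausted=exhausted,
    )


def random_negatives(
    positives: Sequence[InteractionRecord],
    pool: UnlabeledPool,
    ratio: int = DEFAULT_RATIO,
    seed: int = 0,
) -> list[InteractionRecord]:
    """Uniform random negatives for positive-only families.

    Draw ``ratio`` x |positives| peptides (capped by the pool size, with a
    warning) without replacement from the proteome pool, excluding the
    positive peptides, and label them -1 with provenance ``random``.
    """
    if len(pool) == 0:
        raise ValueError("random_negatives: empty pool")
    pos_peptides = {str(r.peptide) for r in positives}
    pool = pool.without(pos_peptides)
    candidates = sorted(pool.peptides)
    quota = ratio * len(positives)
    take = min(quota, len(candidates))
    if take < quota:
        logger.warning(
            "random_negatives: pool smaller than quota (%d < %d); returning all",
            len(candidates),
            quota,
        )
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(candidates), size=take, replace=False)) if take else []
    domain_id = positives[0].domain_id if positives else "unknown"
    return [
        InteractionRecord(
            domain_id=domain_id,
            peptide=Peptide(candidates[i]),
            label=-1,
            provenance="random",
        )
        for i in chosen
    ]
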