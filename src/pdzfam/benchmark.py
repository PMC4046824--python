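"""Decision rules over the published external-validation table.

A packaged table lists 20 experimentally validated mouse PDZ-peptide
interactions with the scores two methods assigned them: the family SVM
(binder iff decision score > 0) and the multi-domain selectivity model
baseline, whose normalised score is the ratio of the raw PSSM score over a
per-domain threshold (binder iff ratio > 1). Because every row is a true
interaction, the binder counts are true-positive counts and the fraction
called is the true positive rate of each method on this set.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

from .records import Peptide

__all__ = [
    "ValidationRecord",
    "ValidationSummary",
    "load_validation_table",
    "read_validation_table",
    "svm_binder",
    "mdsm_binder",
    "validation_summary",
]

SVM_THRESHOLD = 0.0  # binder iff score strictly above
MDSM_THRESHOLD = 1.0  # binder iff ratio strictly above


@dataclass(frozen=True)
class ValidationRecord:
    """One validated interaction with both methods' scores."""

    domain: str
    peptide: Peptide
    svm_score: float
    mdsm_score: float
    pubmed_id: str


def _records_from_frame(df: pd.DataFrame) -> list[ValidationRecord]:
    required = {"domain", "peptide", "svm_score", "mdsm_score", "pubmed_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"validation table missing columns {sorted(missing)}")
    return [
        ValidationRecord(
            domain=str(row.domain),
            peptide=Peptide(row.peptide),
            svm_score=float(row.svm_score),
            mdsm_score=float(row.mdsm_score),
            pubmed_id=str(row.pubmed_id),
        )
        for row in df.itertuples(index=False)
    ]


def read_validation_table(path) -> list[ValidationRecord]:
    """Read a validation table TSV (domain, peptide, svm_score, mdsm_score, pubmed_id)."""
    return _records_from_frame(pd.read_csv(path, sep="\t", dtype={"pubmed_id": str}))


def load_validation_table() -> list[ValidationRecord]:
    """The packaged 20-row validated interaction set."""
    with resources.files("pdzfam.data").joinpath(
        "validated_interactions.tsv"
    ).open() as fh:
        return _records_from_frame(pd.read_csv(fh, sep="\t", dtype={"pubmed_id": str}))


def svm_binder(record: ValidationRecord, threshold: float = SVM_THRESHOLD) -> bool:
    """Binder call from the SVM decision score (strictly above threshold)."""
    return record.svm_score > threshold


def mdsm_binder(record: ValidationRecord, threshold: float = MDSM_THRESHOLD) -> bool:
    """Binder call from the normalised baseline ratio (strictly above 1)."""
    return record.mdsm_score > threshold


@dataclass(frozen=True)
class ValidationSummary:
    svm_tp: int
    svm_tpr: float
    mdsm_tp: int
    mdsm_tpr: float
    total: int


def validation_summary(records: Sequence[ValidationRecord]) -> ValidationSummary:
    """True-positive counts and rates of both methods on validated binders.

    All records are assumed to be true interactions, so TPR is simply the
    fraction of records each decision rule calls a binder.
    """
    if not records:
        raise ValueError("validation summary needs at least one record")
    svm_tp = sum(svm_binder(r) for r in records)
    mdsm_tp = sum(mdsm_binder(r) for r in records)
    n = len(records)
    return ValidationSummary(
        svm_tp=svm_tp,
        svm_tpr=svm_tp / n,
        mdsm_tp=mdsm_tp,
        mdsm_tpr=mdsm_tp / n,
        total=n,
    )
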