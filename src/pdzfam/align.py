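"""Global pairwise alignment and percent identity between domain sequences.

Domain pairs are compared with classic Needleman-Wunsch global alignment
(BLOSUM62, affine gap costs 10 open / 0.5 extend by default) and summarised
as a percent identity over the full alignment length, gap columns included.
The resulting symmetric identity matrix feeds the family clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .alphabet import GAP_CHAR, validate_sequence
from .records import DomainRecord

__all__ = [
    "AlignmentScoring",
    "AlignedPair",
    "global_align",
    "percent_identity",
    "pairwise_identity_matrix",
    "write_identity_matrix",
    "read_identity_matrix",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix plus affine gap costs for global alignment.

    ``gap_open`` and ``gap_extend`` are costs (positive numbers); the first
    gap position in a run costs ``gap_open + gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def build_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped strings and the alignment score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    def __iter__(self):
        return iter((self.aligned_a, self.aligned_b, self.score))


def global_align(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> AlignedPair:
    """Optimal global alignment of two protein sequences.

    Returns an :class:`AlignedPair`; removing gaps from the two gapped
    strings recovers the inputs. Among co-optimal alignments the first
    reported by the (deterministic) traceback is returned.
    """
    a = validate_sequence(a, what="sequence a")
    b = validate_sequence(b, what="sequence b")
    aligner = scoring.build_aligner()
    alignment = aligner.align(a, b)[0]
    return AlignedPair(str(alignment[0]), str(alignment[1]), float(alignment.score))


def percent_identity(pair: AlignedPair, *, denominator: str = "alignment") -> float:
    """Percent identity of an aligned pair, in [0, 100].

    With the default ``denominator="alignment"`` the identity is
    100 x (identical columns) / (alignment length, gap columns included) —
    the convention pinned for the 50% clustering cutoff. The alternative
    ``denominator="shorter"`` divides by the shorter ungapped sequence
    length instead.
    """
    a, b = pair.aligned_a, pair.aligned_b
    if len(a) != len(b):
        raise ValueError("aligned strings must have equal length")
    matches = sum(
        1 for x, y in zip(a, b) if x == y and x != GAP_CHAR
    )
    if denominator == "alignment":
        denom = len(a)
    elif denominator == "shorter":
        denom = min(
            len(a) - a.count(GAP_CHAR),
            len(b) - b.count(GAP_CHAR),
        )
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    if denom == 0:
        raise ValueError("cannot compute identity of empty alignment")
    return 100.0 * matches / denom


def pairwise_identity_matrix(
    domains: Sequence[DomainRecord],
    scoring: AlignmentScoring = DEFAULT_SCORING,
    *,
    denominator: str = "alignment",
) -> pd.DataFrame:
    """Symmetric percent-identity table over a set of domains.

    The diagonal is exactly 100; entry (a, b) is the percent identity of the
    global alignment of the two sequences. Duplicate domain ids are
    rejected.
    """
    if len(domains) == 0:
        raise ValueError("need at least one domain")
    ids = [d.id for d in domains]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate domain ids: {dupes}")
    n = len(domains)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pair = global_align(domains[i].sequence, domains[j].sequence, scoring)
            ident = percent_identity(pair, denominator=denominator)
            mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=ids, columns=ids)


def write_identity_matrix(table: pd.DataFrame, path) -> None:
    """Write an identity matrix as TSV with id header row and column."""
    table.to_csv(path, sep="\t", index_label="id", float_format="%.6g")


def read_identity_matrix(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    return table
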