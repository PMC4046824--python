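"""Proteome-wide scan for candidate C-terminal binders of modelled domains.

Every protein contributes its last five residues as a candidate peptide.
Two biology-motivated filters run before scoring: the peptide must lie in a
disordered segment (mean per-residue disorder score of the last five
residues at or above a cutoff, default 0.4) and the peptide's protein must
share at least one Gene Ontology cellular-component term with the domain's
protein. Surviving peptides are scored by the domain's family model and
ranked by decision score within each domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA20
from .models import TrainedFamilyModel
from .records import Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "ProteomeEntry",
    "ScanHit",
    "ScanSummary",
    "disorder_filter",
    "colocalization_filter",
    "scan_proteome",
    "hits_to_frame",
]

DEFAULT_DISORDER_CUTOFF = 0.4


@dataclass
class ProteomeEntry:
    """A proteome protein with optional disorder scores and GO-CC terms."""

    protein_id: str
    sequence: str
    disorder: Optional[list[float]] = None
    go_terms: Optional[set[str]] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.disorder is not None and len(self.disorder) != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: disorder vector length "
                f"{len(self.disorder)} != sequence length {len(self.sequence)}"
            )

    def cterm_peptide(self) -> Optional[str]:
        if len(self.sequence) < 5:
            return None
        tail = self.sequence[-5:]
        if set(tail) - set(AA20):
            return None
        return tail


@dataclass(frozen=True)
class ScanHit:
    domain_id: str
    family_id: str
    protein_id: str
    peptide: str
    score: float
    probability: float
    rank: int


def disorder_filter(
    entry: ProteomeEntry, cutoff: float = DEFAULT_DISORDER_CUTOFF
) -> bool:
    """Keep iff the mean disorder of the last 5 residues is >= cutoff.

    Raises if the entry has no disorder scores; the caller decides the
    missing-data policy (skip by default in :func:`scan_proteome`).
    """
    if entry.disorder is None:
        raise ValueError(f"{entry.protein_id}: no disorder scores")
    if len(entry.sequence) < 5:
        return False
    return float(np.mean(entry.disorder[-5:])) >= cutoff


def colocalization_filter(
    domain_go: Optional[set[str]], peptide_go: Optional[set[str]]
) -> bool:
    """Keep iff the two GO cellular-component sets share at least one term."""
    if domain_go is None or peptide_go is None:
        raise ValueError("both GO-CC sets must be provided")
    return bool(domain_go & peptide_go)


@dataclass
class ScanSummary:
    """Counts at each filter stage of one scan run."""

    n_proteins: int = 0
    n_with_peptide: int = 0
    n_missing_disorder: int = 0
    n_pass_disorder: int = 0
    per_domain_missing_go: dict[str, int] = field(default_factory=dict)
    per_domain_pass_go: dict[str, int] = field(default_factory=dict)
    n_hits: int = 0

    def to_dict(self) -> dict:
        return {
            "n_proteins": self.n_proteins,
            "n_with_peptide": self.n_with_peptide,
            "n_missing_disorder": self.n_missing_disorder,
            "n_pass_disorder": self.n_pass_disorder,
            "per_domain_missing_go": self.per_domain_missing_go,
            "per_domain_pass_go": self.per_domain_pass_go,
            "n_hits": self.n_hits,
        }


def scan_proteome(
    models: dict[str, TrainedFamilyModel],
    proteome: Sequence[ProteomeEntry],
    domain_go: dict[str, set[str]],
    disorder_cutoff: float = DEFAULT_DISORDER_CUTOFF,
    top_k: Optional[int] = None,
    missing_data_policy: str = "skip",
) -> tuple[list[ScanHit], ScanSummary]:
    """Rank candidate binders of each modelled domain across a proteome.

    ``models`` maps domain id -> that domain's family model; ``domain_go``
    maps domain id -> the GO-CC terms of the domain's protein. Per domain:
    extract last-5 peptides, apply the disorder filter, keep proteins
    sharing a GO-CC term with the domain, score the survivors, sort by
    decision score descending (ties: protein id ascending) and emit the top
    ``top_k`` as ranked hits. Proteins lacking disorder or GO data are
    skipped with a logged count under the default policy, or passed through
    the respective filter with ``missing_data_policy="pass"``.
    """
    if not models:
        raise ValueError("need at least one trained model")
    missing_go_domains = [d for d in models if d not in domain_go]
    if missing_go_domains:
        raise ValueError(
            f"no GO annotation for modelled domains: {sorted(missing_go_domains)}"
        )
    if missing_data_policy not in ("skip", "pass"):
        raise ValueError(f"unknown missing-data policy {missing_data_policy!r}")

    summary = ScanSummary(n_proteins=len(proteome))
    candidates: list[ProteomeEntry] = []
    for entry in proteome:
        if entry.cterm_peptide() is None:
            continue
        summary.n_with_peptide += 1
        if entry.disorder is None:
            summary.n_missing_disorder += 1
            if missing_data_policy == "skip":
                continue
        elif not disorder_filter(entry, cutoff=disorder_cutoff):
            continue
        summary.n_pass_disorder += 1
        candidates.append(entry)

    hits: list[ScanHit] = []
    for domain_id in sorted(models):
        model = models[domain_id]
        dgo = domain_go[domain_id]
        scored: list[tuple[float, float, ProteomeEntry]] = []
        missing_go = 0
        for entry in candidates:
            if entry.go_terms is None:
                missing_go += 1
                if missing_data_policy == "skip":
                    continue
            elif not colocalization_filter(dgo, entry.go_terms):
                continue
            peptide = entry.cterm_peptide()
            score = float(model.decision_score([peptide], domain_id)[0])
            prob = float(model.probability([peptide], domain_id)[0])
            scored.append((score, prob, entry))
        summary.per_domain_missing_go[domain_id] = missing_go
        summary.per_domain_pass_go[domain_id] = len(scored)
        scored.sort(key=lambda t: (-t[0], t[2].protein_id))
        keep = scored if top_k is None else scored[:top_k]
        for rank, (score, prob, entry) in enumerate(keep, start=1):
            hits.append(
                ScanHit(
                    domain_id=domain_id,
                    family_id=model.family_id,
                    protein_id=entry.protein_id,
                    peptide=entry.cterm_peptide(),
                    score=score,
                    probability=prob,
                    rank=rank,
                )
            )
    summary.n_hits = len(hits)
    if summary.n_missing_disorder:
        logger.info(
            "scan: %d proteins lacked disorder data (%s policy)",
            summary.n_missing_disorder,
            missing_data_policy,
        )
    return hits, summary


def hits_to_frame(hits: Sequence[ScanHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain_id": h.domain_id,
                "family_id": h.family_id,
                "protein_id": h.protein_id,
                "peptide": h.peptide,
                "score": h.score,
                "probability": h.probability,
                "rank": h.rank,
            }
            for h in hits
        ],
        columns=[
            "domain_id",
            "family_id",
            "protein_id",
            "peptide",
            "score",
            "probability",
            "rank",
        ],
    )
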