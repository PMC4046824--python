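"""Readers and writers for the package's file formats.

FASTA (domains, proteomes, aligned families) goes through Biopython;
tabular formats (interaction tables, disorder scores, GO annotations) are
TSV via pandas. GO annotations are also accepted in GAF 2.x, keeping only
cellular-component rows.
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .alphabet import GAP_CHAR
from .records import DomainRecord, InteractionRecord, Peptide

logger = logging.getLogger(__name__)

__all__ = [
    "read_domain_fasta",
    "write_domain_fasta",
    "read_alignment_fasta",
    "read_proteome_fasta",
    "read_interaction_table",
    "write_interaction_table",
    "read_disorder_tsv",
    "write_disorder_tsv",
    "read_go_annotations",
    "write_go_tsv",
]


def _organism_from_description(description: str) -> str:
    for token in description.split():
        if token.startswith("organism="):
            return token.split("=", 1)[1]
    return "synthetic"


def read_domain_fasta(path) -> list[DomainRecord]:
    """Read domain records; id = header token before first whitespace.

    An optional ``organism=<tag>`` key in the description sets the organism
    (default "synthetic"). Non-standard residues raise at parse time.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            DomainRecord(
                id=rec.id,
                sequence=str(rec.seq),
                organism=_organism_from_description(rec.description),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_domain_fasta(domains, path) -> None:
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f">{d.id} organism={d.organism}\n{d.sequence}\n")


def read_alignment_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA (family MSA) as id -> gapped sequence."""
    msa = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not msa:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows in {path} have unequal lengths {lengths}")
    return msa


def read_proteome_fasta(path) -> dict[str, str]:
    """Read a proteome FASTA as protein id -> full sequence (upper-cased)."""
    prot = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not prot:
        raise ValueError(f"no FASTA records in {path}")
    return prot


def read_interaction_table(path) -> list[InteractionRecord]:
    """Read an interaction TSV: domain_id, peptide, label[, kd_uM, provenance]."""
    df = pd.read_csv(path, sep="\t", dtype={"domain_id": str, "peptide": str})
    required = {"domain_id", "peptide", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        kd = getattr(row, "kd_uM", None)
        if kd is not None and pd.isna(kd):
            kd = None
        provenance = getattr(row, "provenance", "experimental")
        if provenance is None or pd.isna(provenance):
            provenance = "experimental"
        records.append(
            InteractionRecord(
                domain_id=row.domain_id,
                peptide=Peptide(row.peptide),
                label=int(row.label),
                kd_um=float(kd) if kd is not None else None,
                provenance=provenance,
            )
        )
    return records


def write_interaction_table(records, path) -> None:
    rows = [
        {
            "domain_id": r.domain_id,
            "peptide": str(r.peptide),
            "label": r.label,
            "kd_uM": r.kd_um if r.kd_um is not None else "",
            "provenance": r.provenance,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["domain_id", "peptide", "label", "kd_uM", "provenance"]
    ).to_csv(path, sep="\t", index=False)


def read_disorder_tsv(path) -> dict[str, list[float]]:
    """Per-residue disorder scores: TSV (protein_id, position, score).

    Positions are 1-based and must be contiguous from 1 for each protein;
    scores are in [0, 1]. Returns protein id -> score list.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: dict[str, list[float]] = {}
    for pid, group in df.groupby("protein_id", sort=False):
        group = group.sort_values("position")
        positions = group["position"].to_list()
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError(f"disorder positions for {pid} are not contiguous from 1")
        scores = group["score"].astype(float).to_list()
        if any(not 0.0 <= s <= 1.0 for s in scores):
            raise ValueError(f"disorder scores for {pid} outside [0, 1]")
        out[str(pid)] = scores
    return out


def write_disorder_tsv(disorder: dict[str, list[float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tscore\n")
        for pid, scores in disorder.items():
            for pos, s in enumerate(scores, start=1):
                fh.write(f"{pid}\t{pos}\t{s:.4f}\n")


def read_go_annotations(path, *, fmt: Optional[str] = None) -> dict[str, set[str]]:
    """Protein -> GO cellular-component term sets.

    ``fmt`` is "tsv" (two columns: protein_id, go_term), "gaf" (GAF 2.x,
    keeping only aspect-C rows), or None to sniff: files whose first
    non-blank line starts with "!gaf-version" are GAF.
    """
    path = str(path)
    if fmt is None:
        with open(path) as fh:
            first = ""
            for line in fh:
                if line.strip():
                    first = line
                    break
        fmt = "gaf" if first.lower().startswith("!gaf") else "tsv"
    terms: dict[str, set[str]] = {}
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"protein_id", "go_term"} <= set(df.columns):
            raise ValueError("GO TSV must have columns protein_id, go_term")
        for row in df.itertuples(index=False):
            terms.setdefault(row.protein_id, set()).add(row.go_term)
    elif fmt == "gaf":
        with open(path) as fh:
            for line in fh:
                if line.startswith("!") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    continue
                # GAF columns: 2 = DB object id, 5 = GO id, 9 = aspect
                if fields[8] != "C":
                    continue
                terms.setdefault(fields[1], set()).add(fields[4])
    else:
        raise ValueError(f"unknown GO annotation format {fmt!r}")
    return terms


def write_go_tsv(annotations: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tgo_term\n")
        for pid in annotations:
            for term in sorted(annotations[pid]):
                fh.write(f"{pid}\t{term}\n")
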