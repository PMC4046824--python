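"""Synthetic fixture generators: families, interactions, structures, proteomes.

Every pipeline stage is testable offline from generated inputs that mimic
the statistical structure of the real data: families of ~85-residue domains
sharing a controllable intra-family identity (inter-family identity stays
near the random-sequence baseline), positive peptides drawn from the
C-terminal class I/II/III motif grammars with uniformly random non-motif
negatives, toy two-chain complex structures with scripted inter-residue
distances, and proteomes whose proteins carry per-residue disorder scores
and GO cellular-component terms, with planted binders and single-filter
decoys documented in a manifest. All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alphabet import AA20, HYDROPHOBIC
from .align import pairwise_identity_matrix
from .records import DomainRecord, InteractionRecord, Peptide

__all__ = [
    "MOTIF_CLASSES",
    "generate_family",
    "generate_families",
    "generate_peptide",
    "matches_motif",
    "generate_interactions",
    "generate_toy_structure",
    "generate_proteome",
    "ProteomeFixture",
]

MOTIF_CLASSES = ("I", "II", "III")
_PHI = sorted(HYDROPHOBIC)
_AA = list(AA20)

#: GO-CC terms used by the proteome fixture.
GO_SHARED = "GO:0005886"  # plasma membrane: shared with the domain protein
GO_DOMAIN_EXTRA = "GO:0005737"  # cytoplasm
GO_OTHER = "GO:0005634"  # nucleus: never on the domain protein


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def generate_family(
    n_domains: int = 6,
    identity_target: float = 65.0,
    seed: int = 0,
    family_tag: str = "FAM1",
    length: int = 85,
    organism: str = "synthetic",
) -> tuple[list[DomainRecord], dict[str, str]]:
    """One synthetic domain family and its (trivial, ungapped) alignment.

    An ancestor sequence of ``length`` residues is mutated at a fixed
    number of positions per member, chosen so any two members are
    guaranteed at least ``identity_target`` percent identity; the measured
    pairwise identities are re-checked with the alignment module and an
    error is raised if the target was missed (unachievable target).
    Members are equal length, so the family MSA is the sequences
    themselves.
    """
    if not 2 <= n_domains:
        raise ValueError("a family needs at least 2 domains")
    if not 0 < identity_target <= 100:
        raise ValueError("identity target must be in (0, 100]")
    rng = np.random.default_rng(seed)
    ancestor = _random_sequence(rng, length)
    # m mutations per member: worst-case pairwise identity (L - 2m)/L.
    m = int(np.floor(length * (1 - identity_target / 100.0) / 2))
    records = []
    for i in range(n_domains):
        seq = list(ancestor)
        positions = rng.choice(length, size=m, replace=False)
        for pos in positions:
            choices = [aa for aa in _AA if aa != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        records.append(
            DomainRecord(
                id=f"{family_tag}_D{i + 1:02d}",
                sequence="".join(seq),
                organism=organism,
            )
        )
    ident = pairwise_identity_matrix(records)
    off_diag = ident.to_numpy()[~np.eye(n_domains, dtype=bool)]
    if off_diag.size and off_diag.min() < identity_target:
        raise ValueError(
            f"identity target {identity_target}% unachievable: measured "
            f"minimum {off_diag.min():.1f}%"
        )
    msa = {r.id: r.sequence for r in records}
    return records, msa


def generate_families(
    n_families: int = 3,
    domains_per_family: int = 6,
    identity_target: float = 65.0,
    seed: int = 0,
    length: int = 85,
) -> tuple[list[DomainRecord], dict[str, list[str]]]:
    """Several families from independent ancestors (inter-family identity
    stays near the ~5-15% random baseline, far below the 50% cutoff).

    Returns all domain records plus family tag -> member id list.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_families)
    domains: list[DomainRecord] = []
    families: dict[str, list[str]] = {}
    for k in range(n_families):
        tag = f"FAM{k + 1}"
        recs, _ = generate_family(
            n_domains=domains_per_family,
            identity_target=identity_target,
            seed=int(sub_seeds[k]),
            family_tag=tag,
            length=length,
        )
        domains.extend(recs)
        families[tag] = [r.id for r in recs]
    return domains, families


def generate_peptide(motif_class: str, rng: np.random.Generator) -> str:
    """A random 5-mer drawn from one of the C-terminal motif grammars.

    Class I: x[T/S]x-phi at P-2/P0; class II: phi at P-2 and P0;
    class III: [D/E] at P-2 and phi at P0. P-4/P-3/P-1 are unconstrained.
    """
    if motif_class not in MOTIF_CLASSES:
        raise ValueError(f"motif class must be one of {MOTIF_CLASSES}")
    p = [str(rng.choice(_AA)) for _ in range(5)]
    if motif_class == "I":
        p[2] = str(rng.choice(["T", "S"]))
    elif motif_class == "II":
        p[2] = str(rng.choice(_PHI))
    else:
        p[2] = str(rng.choice(["D", "E"]))
    p[4] = str(rng.choice(_PHI))
    return "".join(p)


def matches_motif(peptide: str, motif_class: str) -> bool:
    """Does a 5-mer satisfy the given class grammar?"""
    p2, p0 = peptide[2], peptide[4]
    if p0 not in HYDROPHOBIC:
        return False
    if motif_class == "I":
        return p2 in ("T", "S")
    if motif_class == "II":
        return p2 in HYDROPHOBIC
    if motif_class == "III":
        return p2 in ("D", "E")
    raise ValueError(f"motif class must be one of {MOTIF_CLASSES}")


def generate_interactions(
    domain_ids: Sequence[str],
    motif_class: str = "I",
    n_pos: int = 30,
    n_neg: int = 150,
    noise: float = 0.0,
    seed: int = 0,
    with_kd: bool = False,
) -> list[InteractionRecord]:
    """Planted-motif interaction records for a family.

    Positives are distinct peptides from the class grammar; negatives are
    uniform random 5-mers rejected against the grammar. A ``noise``
    fraction of labels (rounded down per class) is flipped. Records are
    assigned to the family's domains round-robin; all carry experimental
    provenance. With ``with_kd`` plausible dissociation constants
    consistent with the labels are attached (positives below the 100 uM
    cutoff, negatives above).
    """
    if not domain_ids:
        raise ValueError("need at least one domain id")
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pos_peps: set[str] = set()
    while len(pos_peps) < n_pos:
        pos_peps.add(generate_peptide(motif_class, rng))
    neg_peps: set[str] = set()
    while len(neg_peps) < n_neg:
        pep = _random_sequence(rng, 5)
        if not matches_motif(pep, motif_class) and pep not in pos_peps:
            neg_peps.add(pep)
    records: list[InteractionRecord] = []
    labelled = [(p, 1) for p in sorted(pos_peps)] + [(p, -1) for p in sorted(neg_peps)]
    n_flip_pos = int(noise * n_pos)
    n_flip_neg = int(noise * n_neg)
    flip = set(rng.choice(n_pos, size=n_flip_pos, replace=False)) | {
        n_pos + i for i in rng.choice(n_neg, size=n_flip_neg, replace=False)
    }
    for i, (pep, label) in enumerate(labelled):
        if i in flip:
            label = -label
        kd = None
        if with_kd:
            kd = float(rng.uniform(1, 90)) if label == 1 else float(rng.uniform(150, 900))
        records.append(
            InteractionRecord(
                domain_id=domain_ids[i % len(domain_ids)],
                peptide=Peptide(pep),
                label=label,
                kd_um=kd,
                provenance="experimental",
            )
        )
    return records


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resseq:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{bfac:>6.2f}"
    "          {element:>2s}\n"
)


def generate_toy_structure(
    layout: Sequence[tuple[int, int, float]],
    path,
    n_domain_residues: int = 10,
    domain_chain: str = "A",
    peptide_chain: str = "B",
) -> Path:
    """Write a minimal two-chain PDB file realising a contact layout.

    ``layout`` lists (domain residue index 0-based, peptide position in
    {0..-4}, desired minimum distance in A). Domain residues sit 10 A apart
    along x at y=0; peptide residues default to y=40 (no contact) and a
    contacted peptide residue is moved to the requested distance above its
    domain partner. Each residue gets a CA and a CB atom placed so the
    requested pair distance is exact and every unrequested inter-chain
    residue pair stays beyond 6 A. Layouts reusing a domain residue or a
    peptide position, or asking for a distance outside (0, 6), are
    geometrically infeasible here and rejected.
    """
    dom_used = [d for d, _, _ in layout]
    pep_used = [p for _, p, _ in layout]
    if len(set(dom_used)) != len(dom_used) or len(set(pep_used)) != len(pep_used):
        raise ValueError("layout infeasible: residue reused in several contacts")
    for d, p, dist in layout:
        if not -4 <= p <= 0:
            raise ValueError(f"peptide position {p} outside [-4, 0]")
        if d < 0 or d >= n_domain_residues:
            raise ValueError(f"domain index {d} outside [0, {n_domain_residues})")
        if not 0 < dist < 6:
            raise ValueError(f"distance {dist} infeasible; need 0 < d < 6")

    contact_by_pep = {p + 4: (d, dist) for d, p, dist in layout}
    lines = []
    serial = 1

    def add_residue(chain: str, resseq: int, ca_xyz, cb_xyz) -> None:
        nonlocal serial
        for name, xyz in (("CA", ca_xyz), ("CB", cb_xyz)):
            lines.append(
                _PDB_ATOM.format(
                    serial=serial,
                    name=f" {name}",
                    altloc=" ",
                    resname="ALA",
                    chain=chain,
                    resseq=resseq,
                    icode=" ",
                    x=xyz[0],
                    y=xyz[1],
                    z=xyz[2],
                    occ=1.0,
                    bfac=0.0,
                    element=name[0],
                )
            )
            serial += 1

    for i in range(n_domain_residues):
        add_residue(domain_chain, i + 1, (10.0 * i, 0.0, 0.0), (10.0 * i, -1.5, 0.0))
    lines.append("TER\n")
    for j in range(5):  # 0 -> P-4 ... 4 -> P0
        if j in contact_by_pep:
            d, dist = contact_by_pep[j]
            ca = (10.0 * d, dist, 0.0)
            cb = (10.0 * d, dist + 1.5, 0.0)
        else:
            ca = (10.0 * j, 40.0, 0.0)
            cb = (10.0 * j, 41.5, 0.0)
        add_residue(peptide_chain, j + 1, ca, cb)
    lines.append("TER\nEND\n")
    path = Path(path)
    path.write_text("".join(lines))
    return path


@dataclass
class ProteomeFixture:
    """A generated proteome plus its ground-truth manifest.

    ``manifest`` maps protein id -> {"role", "expected_stage"} where role is
    binder / decoy_disorder / decoy_go / background and expected_stage names
    the filter stage at which the protein should drop out ("disorder",
    "go", or "scored" for proteins that reach scoring).
    """

    proteome: dict[str, str]
    disorder: dict[str, list[float]]
    go_terms: dict[str, set[str]]
    manifest: dict[str, dict[str, str]]
    domain_go: set[str] = field(default_factory=lambda: {GO_SHARED, GO_DOMAIN_EXTRA})

    def entries(self):
        from .scan import ProteomeEntry

        return [
            ProteomeEntry(
                protein_id=pid,
                sequence=seq,
                disorder=self.disorder[pid],
                go_terms=self.go_terms[pid],
            )
            for pid, seq in self.proteome.items()
        ]


def generate_proteome(
    n: int = 200,
    n_binders: int = 5,
    n_decoys_disorder: int = 5,
    n_decoys_go: int = 5,
    motif_class: str = "I",
    seed: int = 0,
    min_length: int = 40,
    max_length: int = 120,
) -> ProteomeFixture:
    """A synthetic proteome with planted binders and single-filter decoys.

    Binders end in a motif-grammar peptide, have a disordered C-terminus
    (last-5 disorder scores in [0.55, 0.95]) and share a GO-CC term with
    the domain protein. Each decoy violates exactly one filter: disorder
    decoys have ordered tails (scores in [0.0, 0.3]), localisation decoys
    carry only a disjoint GO term. Background proteins end in non-grammar
    peptides with uniform-random disorder and mixed GO terms, so some pass
    both filters but none carries the binding motif.
    """
    if n < n_binders + n_decoys_disorder + n_decoys_go:
        raise ValueError("proteome too small for the requested planted proteins")
    rng = np.random.default_rng(seed)
    proteome: dict[str, str] = {}
    disorder: dict[str, list[float]] = {}
    go_terms: dict[str, set[str]] = {}
    manifest: dict[str, dict[str, str]] = {}

    roles = (
        ["binder"] * n_binders
        + ["decoy_disorder"] * n_decoys_disorder
        + ["decoy_go"] * n_decoys_go
        + ["background"] * (n - n_binders - n_decoys_disorder - n_decoys_go)
    )
    for i, role in enumerate(roles):
        pid = f"P{i + 1:04d}"
        length = int(rng.integers(min_length, max_length + 1))
        body = _random_sequence(rng, length - 5)
        if role == "background":
            # Non-hydrophobic P0 breaks every class grammar outright, keeping
            # background tails cleanly separable from planted binder motifs.
            while True:
                tail = _random_sequence(rng, 5)
                if tail[4] not in HYDROPHOBIC:
                    break
        else:
            tail = generate_peptide(motif_class, rng)
        seq = body + tail
        scores = list(rng.uniform(0.0, 1.0, size=length))
        if role in ("binder", "decoy_go"):
            scores[-5:] = list(rng.uniform(0.55, 0.95, size=5))
        elif role == "decoy_disorder":
            scores[-5:] = list(rng.uniform(0.0, 0.3, size=5))
        # background keeps uniform scores: its tail may pass or fail disorder
        if role == "decoy_go":
            terms = {GO_OTHER}
        elif role == "background":
            terms = {GO_SHARED} if rng.random() < 0.5 else {GO_OTHER}
        else:
            terms = {GO_SHARED}
        if role == "binder":
            stage = "scored"
        elif role == "decoy_disorder":
            stage = "disorder"
        elif role == "decoy_go":
            stage = "go"
        else:
            passes_disorder = float(np.mean(scores[-5:])) >= 0.4
            stage = (
                "scored"
                if passes_disorder and GO_SHARED in terms
                else ("disorder" if not passes_disorder else "go")
            )
        proteome[pid] = seq
        disorder[pid] = [round(float(s), 4) for s in scores]
        go_terms[pid] = terms
        manifest[pid] = {"role": role, "expected_stage": stage}
    return ProteomeFixture(
        proteome=proteome, disorder=disorder, go_terms=go_terms, manifest=manifest
    )
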