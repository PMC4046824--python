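"""Binary feature encodings for 5-residue C-terminal peptides.

Two encodings are provided. The sequence encoding maps a 5-mer onto a
100-bit vector (20 bits per position, positions ordered P-4 -> P0,
residues indexed alphabetically). The combined encoding appends, for each
domain/peptide contact pair taken from a reference complex structure, a
400-bit block with a single 1 at 20 * idx(domain residue) + idx(peptide
residue), giving 100 + 400 * n bits for n contact pairs. Contacts are
residue pairs whose minimum heavy-atom distance in the reference structure
is strictly below a cutoff (default 4.5 A), with domain residues expressed
as columns of the family multiple alignment so the same contact features
apply to every family member.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser

from .alphabet import AA_INDEX, GAP_CHAR, validate_sequence
from .records import Peptide

__all__ = [
    "ContactPair",
    "ContactMap",
    "encode_sequence",
    "extract_contacts",
    "map_contacts_to_alignment",
    "encode_combined",
    "write_contact_map",
    "read_contact_map",
]

SEQ_DIM = 100  # 20 residues x 5 positions
PAIR_DIM = 400  # 20 x 20 per contact pair
DEFAULT_CONTACT_CUTOFF = 4.5  # Angstroms, strict '<'


@dataclass(frozen=True)
class ContactPair:
    """One domain/peptide contact.

    ``domain_index`` is a 0-based residue index — into the reference chain
    sequence as extracted, or into MSA columns after
    :func:`map_contacts_to_alignment`. ``peptide_position`` is a peptide
    coordinate in {0, -1, ..., -4} (0 = extreme C-terminus).
    ``min_distance`` is the minimum heavy-atom distance observed (A).
    """

    domain_index: int
    peptide_position: int
    min_distance: float

    def __post_init__(self) -> None:
        if not -4 <= self.peptide_position <= 0:
            raise ValueError(
                f"peptide position must be in [-4, 0], got {self.peptide_position}"
            )
        if self.domain_index < 0:
            raise ValueError("domain index must be >= 0")


@dataclass(frozen=True)
class ContactMap:
    """Ordered, unique list of contact pairs plus the distance cutoff used.

    ``in_msa_coordinates`` records whether domain indices refer to MSA
    columns (required by :func:`encode_combined`) or raw chain positions.
    """

    pairs: tuple[ContactPair, ...]
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    in_msa_coordinates: bool = False

    def __post_init__(self) -> None:
        keys = [(p.domain_index, p.peptide_position) for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("contact pairs must be unique")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n(self) -> int:
        return len(self.pairs)


def encode_sequence(peptide: Peptide | str) -> np.ndarray:
    """One-hot encode a 5-mer into a 100-bit vector (exactly 5 ones).

    Bit ``20*k + aa_index`` is set for position k in fixed order P-4 -> P0;
    residues are indexed alphabetically by one-letter code.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    vec = np.zeros(SEQ_DIM, dtype=np.float64)
    for k, aa in enumerate(peptide.residues):  # k=0 is P-4, k=4 is P0
        vec[20 * k + AA_INDEX[aa]] = 1.0
    return vec


def _heavy_atoms(residue):
    for atom in residue.get_atoms():
        if atom.element != "H":
            yield atom


def _chain_residues(chain):
    """Standard (non-hetero) residues of a chain, in chain order."""
    return [r for r in chain.get_residues() if r.id[0] == " "]


def extract_contacts(
    structure_path,
    domain_chain: str,
    peptide_chain: str,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    *,
    atom_mode: str = "heavy",
) -> ContactMap:
    """Extract domain/peptide contact pairs from a complex structure.

    A (domain residue, peptide residue) pair is a contact iff the minimum
    distance between their atoms is strictly less than ``cutoff`` (default
    4.5 A). ``atom_mode`` selects which atoms enter the scan: ``"heavy"``
    (non-hydrogen, the default convention), ``"all"`` or ``"cb"``
    (C-beta only, C-alpha for glycine). Only the last five residues of the
    peptide chain are considered, indexed P0..P-4 from the C-terminal end.
    Domain residues are reported as 0-based chain sequence indices.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("complex", structure_path)
    model = next(structure.get_models())  # first model only
    chains = {c.id: c for c in model.get_chains()}
    for cid in (domain_chain, peptide_chain):
        if cid not in chains:
            raise ValueError(f"chain {cid!r} not found in {structure_path}")
    dom_residues = _chain_residues(chains[domain_chain])
    pep_residues = _chain_residues(chains[peptide_chain])
    if len(pep_residues) < 5:
        raise ValueError(
            f"peptide chain {peptide_chain!r} has {len(pep_residues)} residues; "
            "need at least 5"
        )
    pep_last5 = pep_residues[-5:]  # index 0 -> P-4, 4 -> P0

    def atoms_of(residue):
        if atom_mode == "heavy":
            return list(_heavy_atoms(residue))
        if atom_mode == "all":
            return list(residue.get_atoms())
        if atom_mode == "cb":
            name = "CB" if "CB" in residue else "CA"
            return [residue[name]] if name in residue else []
        raise ValueError(f"unknown atom_mode {atom_mode!r}")

    pairs: list[ContactPair] = []
    for di, dres in enumerate(dom_residues):
        datoms = atoms_of(dres)
        if not datoms:
            continue
        dcoords = np.array([a.coord for a in datoms])
        for pi, pres in enumerate(pep_last5):
            patoms = atoms_of(pres)
            if not patoms:
                continue
            pcoords = np.array([a.coord for a in patoms])
            diff = dcoords[:, None, :] - pcoords[None, :, :]
            dmin = float(np.sqrt((diff**2).sum(axis=2)).min())
            if dmin < cutoff:
                pairs.append(
                    ContactPair(
                        domain_index=di,
                        peptide_position=pi - 4,  # 0 -> P-4 ... 4 -> P0
                        min_distance=round(dmin, 6),
                    )
                )
    pairs.sort(key=lambda p: (p.domain_index, -p.peptide_position))
    return ContactMap(tuple(pairs), cutoff=cutoff)


def map_contacts_to_alignment(
    contacts: ContactMap, msa: dict[str, str], reference_id: str
) -> ContactMap:
    """Re-express domain contact indices as MSA column indices.

    ``msa`` maps sequence ids to equal-length gapped strings. The reference
    domain (the chain the structure was solved for) must be present; each
    contact's domain residue index is replaced by the alignment column
    holding that residue.
    """
    if reference_id not in msa:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    aligned = msa[reference_id]
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    residue_to_column: list[int] = [
        col for col, ch in enumerate(aligned) if ch != GAP_CHAR
    ]
    mapped = []
    for p in contacts.pairs:
        if p.domain_index >= len(residue_to_column):
            raise ValueError(
                f"contact domain index {p.domain_index} beyond reference length "
                f"{len(residue_to_column)}"
            )
        mapped.append(replace(p, domain_index=residue_to_column[p.domain_index]))
    return ContactMap(tuple(mapped), cutoff=contacts.cutoff, in_msa_coordinates=True)


def encode_combined(
    domain_aligned_seq: str,
    peptide: Peptide | str,
    contacts: ContactMap,
) -> np.ndarray:
    """Concatenate the 100-bit sequence encoding with per-contact 400-bit blocks.

    ``domain_aligned_seq`` is the domain's gapped row of the family MSA;
    contact indices must already be in MSA coordinates. For contact j the
    bit 100 + 400*j + 20*idx(domain residue) + idx(peptide residue) is set.
    A gap at the contact column leaves that pair block all-zero. With an
    empty contact map this reduces to the plain sequence encoding.
    """
    if isinstance(peptide, str):
        peptide = Peptide(peptide)
    if len(contacts) > 0 and not contacts.in_msa_coordinates:
        raise ValueError(
            "contact map must be mapped to MSA coordinates before encoding"
        )
    vec = np.zeros(SEQ_DIM + PAIR_DIM * len(contacts), dtype=np.float64)
    vec[:SEQ_DIM] = encode_sequence(peptide)
    for j, pair in enumerate(contacts.pairs):
        if pair.domain_index >= len(domain_aligned_seq):
            raise ValueError(
                f"contact column {pair.domain_index} beyond aligned sequence "
                f"length {len(domain_aligned_seq)}"
            )
        dom_aa = domain_aligned_seq[pair.domain_index].upper()
        if dom_aa == GAP_CHAR:
            continue  # gap in this family member: block stays zero
        if dom_aa not in AA_INDEX:
            raise ValueError(f"non-standard domain residue {dom_aa!r}")
        pep_aa = peptide.at(pair.peptide_position)
        offset = SEQ_DIM + PAIR_DIM * j
        vec[offset + 20 * AA_INDEX[dom_aa] + AA_INDEX[pep_aa]] = 1.0
    return vec


def write_contact_map(contacts: ContactMap, path) -> None:
    """TSV writer: msa_column (or chain index), peptide position, min distance."""
    with open(path, "w") as fh:
        fh.write("domain_index\tpeptide_position\tmin_distance_A\n")
        for p in contacts.pairs:
            pos = f"P{p.peptide_position}" if p.peptide_position else "P0"
            fh.write(f"{p.domain_index}\t{pos}\t{p.min_distance:.3f}\n")


def read_contact_map(
    path, cutoff: float = DEFAULT_CONTACT_CUTOFF, *, in_msa_coordinates: bool = True
) -> ContactMap:
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            idx, pos, dist = line.rstrip("\n").split("\t")
            pairs.append(
                ContactPair(
                    domain_index=int(idx),
                    peptide_position=int(pos.removeprefix("P") or 0),
                    min_distance=float(dist),
                )
            )
    return ContactMap(tuple(pairs), cutoff=cutoff, in_msa_coordinates=in_msa_coordinates)
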