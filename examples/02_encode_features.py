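"""Encode a C-terminal peptide, with and without structure contacts.

Writes a toy domain-peptide complex with two scripted inter-residue
distances, extracts the contact pairs under the strict 4.5 A heavy-atom
rule, and builds both the 100-bit sequence encoding and the combined
100 + 400*n encoding.
"""

import tempfile
from pathlib import Path

from pdzfam.encoding import (
    encode_combined,
    encode_sequence,
    extract_contacts,
    map_contacts_to_alignment,
)
from pdzfam.synthetic import generate_toy_structure

peptide = "IETHV"  # P-4..P0; P0 = V is the extreme C-terminus
vec = encode_sequence(peptide)
print(f"sequence encoding of {peptide}: length {vec.size}, {int(vec.sum())} ones "
      "(one per 20-bit position block)")

with tempfile.TemporaryDirectory() as tmp:
    # one pair at 3.0 A (a contact) and one at 4.6 A (beyond the cutoff)
    path = generate_toy_structure([(2, 0, 3.0), (5, -2, 4.6)], Path(tmp) / "toy.pdb")
    contacts = extract_contacts(path, domain_chain="A", peptide_chain="B")
    print("extracted contacts (domain residue, peptide position, min dist):",
          [(p.domain_index, f"P{p.peptide_position}", p.min_distance) for p in contacts.pairs])

    msa = {"ref": "AAAAAAAAAA"}  # ungapped family alignment of the reference
    mapped = map_contacts_to_alignment(contacts, msa, "ref")
    combined = encode_combined(msa["ref"], peptide, mapped)
    print(f"combined encoding: length {combined.size} = 100 + 400 x {contacts.n}")
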