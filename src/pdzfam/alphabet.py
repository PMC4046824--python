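"""Amino-acid alphabet conventions shared across the package.

All encodings use the 20 standard residues indexed alphabetically by
one-letter code; peptide positions run P-4 -> P0 where P0 is the extreme
C-terminal residue.
"""

from __future__ import annotations

#: The 20 standard amino acids, alphabetical by one-letter code.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"

#: One-letter code -> index in :data:`AA20`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA20)}

#: Hydrophobic residue set used by the C-terminal motif grammars
#: (phi in the class I/II/III consensus patterns). Config-exposed pin.
HYDROPHOBIC: frozenset[str] = frozenset("AVILFMWY")

#: Peptide positions, N- to C-terminal order. P0 is the last residue.
PEPTIDE_POSITIONS: tuple[str, ...] = ("P-4", "P-3", "P-2", "P-1", "P0")

GAP_CHAR = "-"


class AlphabetError(ValueError):
    """A sequence contains a character outside the 20-letter alphabet."""


def validate_sequence(seq: str, *, what: str = "sequence") -> str:
    """Return ``seq`` upper-cased after checking it is non-empty and standard.

    Raises
    ------
    ValueError
        If the sequence is empty.
    AlphabetError
        If any character is not one of the 20 standard amino acids.
    """
    if not seq:
        raise ValueError(f"empty {what}")
    seq = seq.upper()
    bad = set(seq) - set(AA20)
    if bad:
        raise AlphabetError(
            f"{what} contains non-standard characters: {sorted(bad)!r}"
        )
    return seq
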