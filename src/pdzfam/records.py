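"""Core record types: domains, peptides and interaction records."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .alphabet import validate_sequence

ORGANISMS = ("human", "mouse", "fly", "worm", "synthetic")

#: Dissociation-constant cutoff (micromolar) separating binders from
#: non-binders: K_D <= 100 uM is a positive interaction.
KD_CUTOFF_UM = 100.0

PROVENANCES = ("experimental", "ssl", "random")


@dataclass(frozen=True)
class DomainRecord:
    """A named domain sequence with an organism tag."""

    id: str
    sequence: str
    organism: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, what=f"domain {self.id}")
        )
        if self.organism not in ORGANISMS:
            raise ValueError(
                f"unknown organism {self.organism!r}; expected one of {ORGANISMS}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Peptide:
    """A 5-residue C-terminal peptide, positions P-4..P0 (P0 = C-terminus)."""

    residues: str

    def __post_init__(self) -> None:
        seq = validate_sequence(self.residues, what="peptide")
        if len(seq) != 5:
            raise ValueError(
                f"peptide must have exactly 5 residues, got {len(seq)}: {seq!r}"
            )
        object.__setattr__(self, "residues", seq)

    def __str__(self) -> str:
        return self.residues

    def __len__(self) -> int:
        return 5

    def at(self, position: int) -> str:
        """Residue at peptide coordinate ``position`` in {0, -1, .., -4}.

        ``at(0)`` is the extreme C-terminal residue (P0), ``at(-2)`` the
        residue two upstream of it (P-2).
        """
        if not -4 <= position <= 0:
            raise ValueError(f"peptide position must be in [-4, 0], got {position}")
        return self.residues[4 + position]


@dataclass(frozen=True)
class InteractionRecord:
    """One (domain, peptide) observation with its class label.

    ``label`` is +1 for a binder, -1 for a non-binder. When a dissociation
    constant is given, the label must agree with the 100 uM cutoff.
    ``provenance`` records how the label was obtained: measured
    (``experimental``), produced by self-training (``ssl``) or drawn at
    random from a proteome pool (``random``). Only experimental records may
    enter test sets.
    """

    domain_id: str
    peptide: Peptide
    label: int
    kd_um: Optional[float] = None
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        if isinstance(self.peptide, str):  # convenience coercion
            object.__setattr__(self, "peptide", Peptide(self.peptide))
        if self.label not in (-1, 1):
            raise ValueError(f"label must be -1 or +1, got {self.label}")
        if self.provenance not in PROVENANCES:
            raise ValueError(
                f"provenance must be one of {PROVENANCES}, got {self.provenance!r}"
            )
        if self.kd_um is not None:
            if self.kd_um <= 0:
                raise ValueError("K_D must be positive")
            implied = 1 if self.kd_um <= KD_CUTOFF_UM else -1
            if implied != self.label:
                raise ValueError(
                    f"label {self.label:+d} inconsistent with K_D "
                    f"{self.kd_um} uM under the {KD_CUTOFF_UM} uM cutoff"
                )
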