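"""Shared fixtures: synthetic families, interactions, structures, proteomes.

Everything is generated programmatically with fixed seeds; session scope
keeps the alignment- and SVM-heavy fixtures cheap to reuse.
"""

from __future__ import annotations

import pytest

from pdzfam.align import pairwise_identity_matrix
from pdzfam.synthetic import (
    generate_families,
    generate_interactions,
    generate_proteome,
    generate_toy_structure,
)

GRID4 = tuple((2.0**c, 2.0**g) for c in (-1, 3) for g in (-9, -5))
GRID16 = tuple((2.0**c, 2.0**g) for c in (-1, 1, 3, 5) for g in (-9, -7, -5, -3))


@pytest.fixture(scope="session")
def planted_domains():
    """3 families x 6 domains, intra-identity >= 65%, independent ancestors."""
    domains, families = generate_families(
        n_families=3, domains_per_family=6, identity_target=65.0, seed=11
    )
    return domains, families


@pytest.fixture(scope="session")
def planted_identity(planted_domains):
    domains, _ = planted_domains
    return pairwise_identity_matrix(domains)


@pytest.fixture(scope="session")
def class1_records():
    """Clean class-I family: 30 positives, 150 negatives, two domains."""
    return generate_interactions(
        ["FAM1_D01", "FAM1_D02"], "I", n_pos=30, n_neg=150, noise=0.0, seed=0
    )


@pytest.fixture(scope="session")
def proteome_fixture():
    """200-protein proteome with 5 planted binders and 5+5 decoys."""
    return generate_proteome(n=200, seed=4)


@pytest.fixture()
def toy_structure(tmp_path):
    """Factory writing a toy two-chain complex for a given contact layout."""

    def _make(layout, **kwargs):
        return generate_toy_structure(layout, tmp_path / "toy.pdb", **kwargs)

    return _make
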