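"""Global alignment and percent-identity behaviour."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdzfam.align import (
    AlignedPair,
    AlignmentScoring,
    global_align,
    pairwise_identity_matrix,
    percent_identity,
    read_identity_matrix,
    write_identity_matrix,
)
from pdzfam.alphabet import AA20, AlphabetError
from pdzfam.io import read_domain_fasta, write_domain_fasta
from pdzfam.records import DomainRecord

seqs = st.text(alphabet=AA20, min_size=1, max_size=25)


def brute_force_best_score(a: str, b: str, scoring: AlignmentScoring) -> float:
    """Enumerate every global alignment and score it independently.

    Affine gap runs cost open + extend * length; substitution scores come
    straight from the matrix. Feasible for sequences up to ~6 residues.
    """
    matrix = __import__("Bio.Align.substitution_matrices", fromlist=["load"]).load(
        scoring.matrix_name
    )

    def score(cols) -> float:
        total = 0.0
        for gap_row in (0, 1):
            run = 0
            for col in cols:
                if col[gap_row] == "-":
                    run += 1
                elif run:
                    total -= scoring.gap_open + scoring.gap_extend * run
                    run = 0
            if run:
                total -= scoring.gap_open + scoring.gap_extend * run
        total += sum(matrix[c[0], c[1]] for c in cols if "-" not in c)
        return total

    best = -np.inf

    def rec(i, j, cols):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        pair = global_align("ACDEF", "ACDEF")
        assert pair.aligned_a == pair.aligned_b == "ACDEF"

    def test_single_substitution_stays_ungapped(self):
        pair = global_align("ACDEF", "ACDEG")
        assert len(pair.aligned_a) == 5
        assert "-" not in pair.aligned_a + pair.aligned_b

    def test_gap_removal_recovers_inputs(self):
        a, b = "ACQQQDEKW", "ACDE"
        pair = global_align(a, b)
        assert pair.aligned_a.replace("-", "") == a
        assert pair.aligned_b.replace("-", "") == b

    @pytest.mark.parametrize("a,b", [("A", ""), ("", "ACD")])
    def test_empty_sequence_rejected(self, a, b):
        with pytest.raises(ValueError, match="empty"):
            global_align(a, b)

    def test_illegal_character_rejected(self):
        with pytest.raises(AlphabetError):
            global_align("ACXJ", "ACDE")

    def test_optimality_matches_exhaustive_enumeration(self):
        """For short sequences the score equals the brute-force maximum."""
        scoring = AlignmentScoring()
        rng = np.random.default_rng(42)
        cases = [("ACDEF", "ACDEG"), ("AC", "WWAC"), ("W", "W")]
        for _ in range(8):
            n, m = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list(AA20), size=n))
            b = "".join(rng.choice(list(AA20), size=m))
            cases.append((a, b))
        for a, b in cases:
            expected = brute_force_best_score(a, b, scoring)
            assert global_align(a, b, scoring).score == pytest.approx(expected)


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "aligned_a,aligned_b,expected",
        [
            ("ACDEFGHIKL", "ACDEFGHIKL", 100.0),
            ("ACDEF", "ACDEG", 80.0),  # 4 matching columns / 5
            ("AC-DE", "ACQDE", 80.0),  # gap column counted in denominator
        ],
    )
    def test_hand_counted_identities(self, aligned_a, aligned_b, expected):
        pair = AlignedPair(aligned_a, aligned_b, 0.0)
        assert percent_identity(pair) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            AlignedPair("ACD", "AC", 0.0)

    def test_shorter_sequence_denominator(self):
        pair = AlignedPair("AC-DE", "ACQDE", 0.0)
        assert percent_identity(pair, denominator="shorter") == pytest.approx(100.0)

    @given(a=seqs, b=seqs)
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_self_identity_and_range(self, a, b):
        ab = percent_identity(global_align(a, b))
        ba = percent_identity(global_align(b, a))
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab <= 100.0
        assert percent_identity(global_align(a, a)) == pytest.approx(100.0)


class TestIdentityMatrix:
    def test_single_domain(self):
        table = pairwise_identity_matrix([DomainRecord("d1", "ACDEFGH")])
        assert table.shape == (1, 1) and table.iloc[0, 0] == 100.0

    def test_identical_pair_off_diagonal_100(self):
        doms = [DomainRecord("a", "ACDEFGH"), DomainRecord("b", "ACDEFGH")]
        table = pairwise_identity_matrix(doms)
        assert table.loc["a", "b"] == pytest.approx(100.0)

    def test_matches_per_pair_recomputation(self):
        rng = np.random.default_rng(3)
        doms = [
            DomainRecord(f"d{i}", "".join(rng.choice(list(AA20), size=80)))
            for i in range(4)
        ]
        table = pairwise_identity_matrix(doms)
        for i in range(4):
            for j in range(4):
                expected = (
                    100.0
                    if i == j
                    else percent_identity(
                        global_align(doms[i].sequence, doms[j].sequence)
                    )
                )
                assert table.iloc[i, j] == pytest.approx(expected)
        values = table.to_numpy()
        assert np.allclose(values, values.T)
        assert ((0 <= values) & (values <= 100)).all()

    def test_duplicate_ids_rejected(self):
        doms = [DomainRecord("d", "ACDE"), DomainRecord("d", "ACDF")]
        with pytest.raises(ValueError, match="duplicate"):
            pairwise_identity_matrix(doms)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity_matrix([])

    def test_tsv_round_trip(self, tmp_path):
        doms = [DomainRecord("a", "ACDEFGHIKL"), DomainRecord("b", "ACDEFGWIKL")]
        table = pairwise_identity_matrix(doms)
        path = tmp_path / "ident.tsv"
        write_identity_matrix(table, path)
        loaded = read_identity_matrix(path)
        assert np.allclose(loaded.to_numpy(), table.to_numpy())
        assert list(loaded.index) == ["a", "b"]


def test_domain_fasta_round_trip(tmp_path):
    doms = [
        DomainRecord("dom1", "ACDEFG", organism="human"),
        DomainRecord("dom2", "MKWYTS", organism="mouse"),
    ]
    path = tmp_path / "doms.fa"
    write_domain_fasta(doms, path)
    loaded = read_domain_fasta(path)
    assert loaded == doms
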