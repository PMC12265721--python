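import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapmerscan.kmer_engine import (
    Kmer,
    canonicalize,
    count_kmers,
    homopolymer_compress,
    kmer_to_string,
    reverse_complement,
    scan_sequence,
)
from conftest import make_assembly
from oracles import canonical_kmer, compress_naive, count_kmers_naive, random_dna

dna = st.text(alphabet="ACGT", min_size=0, max_size=60)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=60)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected", [("AACG", "CGTT"), ("ACGT", "ACGT"), ("N", "N"), ("", "")]
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError, match="invalid base"):
            reverse_complement("ACXT")

    @settings(deadline=None)
    @given(dna_n)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestCanonicalize:
    def test_revcomp_smaller_wins(self):
        assert canonicalize("TTTT") == canonicalize("AAAA") == Kmer(code=0, k=4)

    def test_palindrome_fixed_point(self):
        km = canonicalize("ACGT")
        assert km is not None and kmer_to_string(km.code, 4) == "ACGT"

    def test_n_gives_none(self):
        assert canonicalize("ACNG") is None

    @settings(deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=12))
    def test_matches_string_oracle(self, window):
        km = canonicalize(window)
        expect = canonical_kmer(window)
        if expect is None:
            assert km is None
        else:
            assert kmer_to_string(km.code, km.k) == expect


class TestCountKmers:
    def test_hand_enumerated_example(self):
        asm = make_assembly("hap1", {"s": "ACGTACGT"})
        ms = count_kmers(asm, 4)
        assert ms.to_dict() == {"ACGT": 2, "CGTA": 2, "GTAC": 1}
        assert ms.n_occurrences == 5 and ms.n_distinct == 3

    def test_windows_spanning_n_skipped(self):
        ms = count_kmers(make_assembly("hap1", {"s": "ACNGT"}), 3)
        assert ms.n_distinct == 0 and ms.n_occurrences == 0

    def test_record_shorter_than_k_contributes_nothing(self):
        ms = count_kmers(make_assembly("hap1", {"a": "ACG", "b": "ACGTACGT"}), 4)
        assert ms.n_occurrences == 5

    def test_greedy_mode_counts_compressed(self):
        # "AAAACCCCGGGG" compresses to "ACG": a single k=3 window
        ms = count_kmers(make_assembly("hap1", {"s": "AAAACCCCGGGG"}), 3, mode="greedy")
        assert ms.to_dict() == {"ACG": 1}

    @pytest.mark.parametrize("k", [0, 32, -1])
    def test_k_bounds(self, k):
        with pytest.raises(ValueError, match="k must be"):
            count_kmers(make_assembly("hap1", {"s": "ACGT"}), k)

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_matches_naive_oracle_on_random_sequences(self, rng, k):
        for _ in range(20):
            seqs = {
                f"s{i}": random_dna(rng, int(rng.integers(k, 300)))
                for i in range(int(rng.integers(1, 4)))
            }
            ms = count_kmers(make_assembly("hap1", seqs), k)
            assert ms.to_dict() == count_kmers_naive(list(seqs.values()), k)

    def test_strand_symmetry(self, rng):
        seqs = {f"s{i}": random_dna(rng, 200) for i in range(3)}
        rc = {sid: reverse_complement(s) for sid, s in seqs.items()}
        a = count_kmers(make_assembly("hap1", seqs), 7)
        b = count_kmers(make_assembly("hap1", rc), 7)
        assert a.to_dict() == b.to_dict()

    def test_occurrence_count_identity(self, rng):
        # n_occurrences == valid windows == m - windows spanning N
        seq = "".join(rng.choice(list("ACGTN"), 500, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        k = 6
        ms = count_kmers(make_assembly("hap1", {"s": seq}), k)
        valid = sum(
            1 for i in range(len(seq) - k + 1) if "N" not in seq[i : i + k]
        )
        assert ms.n_occurrences == valid


class TestHomopolymerCompress:
    def test_definition_example(self):
        c = homopolymer_compress("AAATTTGGC")
        assert c.bases == "ATGC"
        assert c.origin.tolist() == [0, 3, 6, 8]
        assert c.original_length == 9

    def test_already_compressed_is_identity(self):
        c = homopolymer_compress("ACGT")
        assert c.bases == "ACGT" and c.origin.tolist() == [0, 1, 2, 3]

    def test_empty(self):
        c = homopolymer_compress("")
        assert c.bases == "" and c.origin.size == 0 and c.original_length == 0

    @settings(deadline=None)
    @given(dna_n)
    def test_idempotent_never_longer_matches_oracle(self, seq):
        c = homopolymer_compress(seq)
        assert c.bases == compress_naive(seq)
        assert len(c.bases) <= len(seq)
        assert homopolymer_compress(c.bases).bases == c.bases
        # origin strictly increasing and starts at 0
        if c.origin.size:
            assert c.origin[0] == 0
            assert (np.diff(c.origin) > 0).all()


class TestScanSequence:
    def test_greedy_positions_are_run_starts(self):
        scan = scan_sequence("AAAACCCCGGGG", 3, mode="greedy")
        assert scan.positions.tolist() == [0]  # window "ACG" starts at run start 0
        assert scan.valid.tolist() == [True]

    def test_full_mode_positions_implicit(self):
        scan = scan_sequence("ACGTACGT", 4)
        assert scan.origin is None
        assert scan.positions.tolist() == [0, 1, 2, 3, 4]
        assert scan.hit_positions(np.array([1, 0, 1, 0, 1], bool)).tolist() == [0, 2, 4]
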