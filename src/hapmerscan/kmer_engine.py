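"""Canonical k-mer machinery.

Every k-mer is represented by the 2-bit packed integer code of the
canonical form — the numerically smaller of the k-mer and its reverse
complement under the A=0, C=1, G=2, T=3 encoding (most significant base
first), which coincides with lexicographic order on ACGT.  With k capped at
31 a code fits in one unsigned 64-bit integer, so whole-assembly multisets
are plain sorted uint64 arrays: compact enough for ~10^8 distinct keys and
amenable to vectorised set algebra.

Counting has two modes.  ``full`` scans the normalised bases directly.
``greedy`` first homopolymer-compresses each sequence (each run of one base
collapsed to a single base) and scans the compressed string with the same
k; positions found in compressed space are projected back to original
coordinates at each run's first base.  Compression trades sensitivity for
robustness to homopolymer-length errors in large genomes.

Windows containing an N contribute nothing in either mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numba as nb
import numpy as np

from ._kernels import sorted_unique_counts
from .sequence_io import HaplotypeAssembly

DEFAULT_K = 28
MAX_K = 31

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")


class Kmer(NamedTuple):
    """A canonical k-mer: 2-bit packed integer code plus its length."""

    code: int
    k: int


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N self-complements)."""
    if any(c not in "ACGTN" for c in set(seq)):
        bad = next(c for c in seq if c not in "ACGTN")
        raise ValueError(f"invalid base {bad!r}")
    return seq.translate(_COMP)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Map a normalised sequence to uint8 codes (A/C/G/T -> 0..3, N -> 255)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@nb.njit(cache=True)
def _scan_codes(b, k):  # pragma: no cover — exercised through scan_sequence
    n = b.shape[0]
    m = n - k + 1
    canon = np.zeros(m, np.uint64)
    valid = np.zeros(m, np.bool_)
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = 0
    rev = 0
    run = 0
    for i in range(n):
        c = b[i]
        if c > 3:
            run = 0
        else:
            ci = np.int64(c)
            fwd = ((fwd << 2) | ci) & mask
            rev = (rev >> 2) | ((3 - ci) << shift)
            run += 1
        j = i - k + 1
        if j >= 0 and run >= k:
            canon[j] = np.uint64(fwd if fwd < rev else rev)
            valid[j] = True
    return canon, valid


@dataclass
class CompressedSeq:
    """Homopolymer-compressed bases with a map back to original coordinates.

    ``origin[i]`` is the original 0-based index of the first base of the
    run that produced compressed position ``i``.
    """

    bases: str
    origin: np.ndarray
    original_length: int


def homopolymer_compress(seq: str) -> CompressedSeq:
    if not seq:
        return CompressedSeq(bases="", origin=np.empty(0, dtype=np.int64), original_length=0)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    keep = np.empty(arr.size, dtype=bool)
    keep[0] = True
    np.not_equal(arr[1:], arr[:-1], out=keep[1:])
    origin = np.flatnonzero(keep).astype(np.int64)
    return CompressedSeq(
        bases=arr[keep].tobytes().decode("ascii"),
        origin=origin,
        original_length=len(seq),
    )


@dataclass
class KmerScan:
    """Per-position canonical codes for one sequence.

    ``valid`` marks windows free of N.  Original-coordinate k-mer start
    positions are implicit (window index) in full mode; in greedy mode
    ``origin`` maps compressed window indices to the run-start coordinate.
    All downstream tallies derive from these arrays.
    """

    k: int
    mode: str
    codes: np.ndarray              # uint64, one per window
    valid: np.ndarray              # bool
    origin: np.ndarray | None      # int64 original coords (greedy), None in full mode
    length: int                    # original sequence length

    @property
    def valid_codes(self) -> np.ndarray:
        return self.codes[self.valid]

    @property
    def positions(self) -> np.ndarray:
        """Original-coordinate start of every window (materialised)."""
        if self.origin is not None:
            return self.origin
        return np.arange(self.codes.size, dtype=np.int64)

    def hit_positions(self, mask: np.ndarray) -> np.ndarray:
        """Original-coordinate starts of masked windows, without
        materialising the full position array in full mode."""
        if self.origin is not None:
            return self.origin[mask]
        return np.flatnonzero(mask)


def _check_k(k: int) -> None:
    if not (1 <= k <= MAX_K):
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")


def scan_sequence(bases: str, k: int, mode: str = "full") -> KmerScan:
    """Canonical k-mer codes for every window of one sequence."""
    _check_k(k)
    if mode not in ("full", "greedy"):
        raise ValueError(f"mode must be 'full' or 'greedy', got {mode!r}")
    length = len(bases)
    if mode == "greedy":
        comp = homopolymer_compress(bases)
        scan_bases, origin = comp.bases, comp.origin
    else:
        scan_bases, origin = bases, None
    m = len(scan_bases) - k + 1
    if m <= 0:
        empty = np.empty(0, dtype=np.uint64)
        return KmerScan(k, mode, empty, np.empty(0, dtype=bool),
                        None if origin is None else origin[:0], length)
    codes, valid = _scan_codes(encode_bases(scan_bases), k)
    return KmerScan(k, mode, codes, valid,
                    None if origin is None else origin[:m], length)


def canonicalize(window: str) -> Optional[Kmer]:
    """Canonical form of a single window, or None if it contains non-ACGT."""
    k = len(window)
    scan = scan_sequence(window, k)
    if scan.valid.size == 0 or not scan.valid[0]:
        return None
    return Kmer(code=int(scan.codes[0]), k=k)


def kmer_to_string(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append("ACGT"[(code >> shift) & 3])
    return "".join(out)


@dataclass
class KmerMultiset:
    """Canonical k-mer -> occurrence count for one assembly (or sequence).

    Stored as parallel sorted arrays (unique uint64 codes, int64 counts).
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def n_occurrences(self) -> int:
        return int(self.counts.sum())

    def count_of(self, code: int) -> int:
        i = np.searchsorted(self.codes, np.uint64(code))
        if i < self.codes.size and self.codes[i] == np.uint64(code):
            return int(self.counts[i])
        return 0

    def to_dict(self) -> dict[str, int]:
        return {
            kmer_to_string(int(c), self.k): int(n)
            for c, n in zip(self.codes, self.counts)
        }


def multiset_from_code_arrays(code_arrays: list[np.ndarray], k: int) -> KmerMultiset:
    """Aggregate valid canonical codes from several sequences into one multiset."""
    if code_arrays:
        allcodes = np.concatenate(code_arrays)
    else:
        allcodes = np.empty(0, dtype=np.uint64)
    codes, counts = sorted_unique_counts(allcodes)
    return KmerMultiset(k=k, codes=codes, counts=counts)


def count_kmers(assembly: HaplotypeAssembly, k: int = DEFAULT_K, mode: str = "full") -> KmerMultiset:
    """Canonical k-mer multiset over all sequences of one haplotype."""
    _check_k(k)
    arrays = [scan_sequence(rec.bases, k, mode).valid_codes for rec in assembly]
    return multiset_from_code_arrays(arrays, k)


def dump_kmers(ms: KmerMultiset, path) -> None:
    """Debug TSV of (kmer, count), sorted by code."""
    with open(path, "wt") as fh:
        fh.write("kmer\tcount\n")
        for c, n in zip(ms.codes, ms.counts):
            fh.write(f"{kmer_to_string(int(c), ms.k)}\t{int(n)}\n")
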