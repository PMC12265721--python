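"""Hap-mer negation, location, and density tracks.

A hap-mer is a canonical k-mer present in one haplotype assembly and
absent from the other.  Negating the two assemblies' k-mer sets leaves the
k-mers created by heterozygous differences between the haplotypes; their
genomic density is roughly uniform along autosomes but strongly elevated
across a non-recombining sex-limited region, which is the signal the whole
workflow is built around.

Hap-mer status is presence/absence of distinct canonical k-mers: a k-mer
occurring five times in hap1 and never in hap2 is one hap-mer with five
located occurrences.  Density tracks count occurrences (windowed by the
k-mer start position); distinct counts are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import hash_build, member_mask, setdiff_sorted, sorted_unique
from .kmer_engine import KmerMultiset, KmerScan, scan_sequence
from .sequence_io import HaplotypeAssembly, SequenceRecord

DEFAULT_WINDOW = 1_000_000


@dataclass
class HapmerSet:
    """Canonical k-mer codes unique to one haplotype (sorted uint64)."""

    haplotype: str
    k: int
    codes: np.ndarray
    _table: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.codes.size)

    def contains(self, codes: np.ndarray) -> np.ndarray:
        if self._table is None:
            self._table = hash_build(self.codes)
        return member_mask(codes, self._table)


def negate(ms1: KmerMultiset, ms2: KmerMultiset) -> tuple[HapmerSet, HapmerSet]:
    """Set-difference the two haplotypes' distinct k-mers.

    Presence/absence semantics: within-assembly multiplicity does not
    disqualify a hap-mer.
    """
    if ms1.k != ms2.k:
        raise ValueError(f"k mismatch: {ms1.k} != {ms2.k}")
    only1 = setdiff_sorted(ms1.codes, ms2.codes)
    only2 = setdiff_sorted(ms2.codes, ms1.codes)
    return (
        HapmerSet(haplotype="hap1", k=ms1.k, codes=only1),
        HapmerSet(haplotype="hap2", k=ms2.k, codes=only2),
    )


@dataclass
class HapmerOccurrences:
    """Located hap-mer occurrences on one assembly.

    ``positions[seq_id]`` holds ascending original-coordinate k-mer starts;
    ``codes[seq_id]`` the matching canonical codes.  Iteration yields
    (seq_id, position) pairs in deterministic (sequence order, position)
    order.
    """

    haplotype: str
    k: int
    seq_order: list[str] = field(default_factory=list)
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    codes: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(int(p.size) for p in self.positions.values())

    def __iter__(self):
        for sid in self.seq_order:
            for p in self.positions[sid]:
                yield sid, int(p)


def locate_hapmers(
    assembly: HaplotypeAssembly,
    hapmers: HapmerSet,
    mode: str = "full",
    scans: dict[str, KmerScan] | None = None,
) -> HapmerOccurrences:
    """Find every occurrence of the haplotype's hap-mers on its assembly.

    ``scans`` may carry precomputed per-sequence KmerScan objects (the
    pipeline computes them once and reuses them across stages).
    """
    occ = HapmerOccurrences(haplotype=assembly.label, k=hapmers.k)
    for rec in assembly:
        scan = scans[rec.id] if scans is not None else scan_sequence(rec.bases, hapmers.k, mode)
        hit = scan.valid & hapmers.contains(scan.codes)
        occ.seq_order.append(rec.id)
        occ.positions[rec.id] = scan.hit_positions(hit)
        occ.codes[rec.id] = scan.codes[hit]
    return occ


@dataclass
class HapmerProfile:
    """Per-sequence hap-mer tallies for one haplotype."""

    haplotype: str
    table: pd.DataFrame  # seq_id, length_bp, hapmer_occurrences, hapmer_distinct, density_per_mb


def build_profile(assembly: HaplotypeAssembly, occurrences: HapmerOccurrences) -> HapmerProfile:
    rows = []
    for rec in assembly:
        pos = occurrences.positions.get(rec.id, np.empty(0, dtype=np.int64))
        codes = occurrences.codes.get(rec.id, np.empty(0, dtype=np.uint64))
        n_occ = int(pos.size)
        rows.append(
            {
                "seq_id": rec.id,
                "length_bp": rec.length,
                "hapmer_occurrences": n_occ,
                "hapmer_distinct": int(sorted_unique(codes).size),
                "density_per_mb": n_occ * 1e6 / rec.length,
            }
        )
    return HapmerProfile(haplotype=assembly.label, table=pd.DataFrame(rows))


@dataclass
class WindowTrack:
    """Fixed-width windowed hap-mer occurrence track for one sequence.

    Windows tile [0, length) exactly; the last window is truncated at the
    sequence end and densities are normalised by the actual span.
    """

    seq_id: str
    window_size: int
    starts: np.ndarray
    ends: np.ndarray
    occurrences: np.ndarray
    density_per_mb: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)


def build_window_track(
    record: SequenceRecord,
    positions: np.ndarray,
    window_size: int = DEFAULT_WINDOW,
    k: int | None = None,
) -> WindowTrack:
    """Assign occurrences to tiling windows by k-mer start position."""
    if k is not None and window_size < k:
        raise ValueError(f"window_size {window_size} < k {k}")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    L = record.length
    n_win = max(1, -(-L // window_size))
    starts = np.arange(n_win, dtype=np.int64) * window_size
    ends = np.minimum(starts + window_size, L)
    counts = np.bincount(
        np.asarray(positions, dtype=np.int64) // window_size, minlength=n_win
    ).astype(np.int64)
    spans = (ends - starts).astype(np.float64)
    return WindowTrack(
        seq_id=record.id,
        window_size=window_size,
        starts=starts,
        ends=ends,
        occurrences=counts,
        density_per_mb=counts * 1e6 / spans,
    )


def write_results(profiles: list[HapmerProfile], path: str | Path) -> None:
    """The per-sequence results TSV: one row per (haplotype, sequence)."""
    frames = []
    for prof in profiles:
        t = prof.table.copy()
        t.insert(0, "haplotype", prof.haplotype)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_windows_bed(tracks: dict[tuple[str, str], WindowTrack], path: str | Path) -> None:
    """Window tracks as BED4+: chrom, start, end, name=haplotype, score, density."""
    with open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\thaplotype\thapmer_occurrences\tdensity_per_mb\n")
        for (hap, _sid), tr in tracks.items():
            for s, e, n, d in zip(tr.starts, tr.ends, tr.occurrences, tr.density_per_mb):
                fh.write(f"{tr.seq_id}\t{s}\t{e}\t{hap}\t{n}\t{d:.6f}\n")
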