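"""Windowed haplotype-identity proxy and segment calling per homolog pair.

For each paired sequence, every valid k-mer window is probed against the
partner sequence's whole-sequence distinct k-mer set; the per-window
fraction of shared windows is a monotone proxy for alignment identity
(never reported as percent identity).  Probing against the whole partner
set rather than the matching window means inversions and translocations
within a chromosome do not spuriously depress identity.

On a sex-chromosome pair, windows inside the sex-limited region show a
sharp drop in shared fraction together with a rise in hap-mer density —
two sides of the same signal — while a pseudoautosomal region stays at
background identity.  Segments of consecutive low-identity windows are
reported as sex-limited candidates; high-identity terminal runs flanking
them are reported as PAR candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import hash_build, member_mask, setdiff_sorted, sorted_unique
from ._util import true_runs
from .hapmer_core import DEFAULT_WINDOW
from .homolog_pairing import HomologPair
from .kmer_engine import KmerScan, scan_sequence
from .sequence_io import HaplotypeAssembly


@dataclass
class IdentityTrack:
    """Per-window shared-k-mer fraction and hap-mer density for one pair.

    ``table`` has one row per window per direction: haplotype, seq_id,
    start, end, n_valid, shared_fraction (NaN when the window has no valid
    k-mer), hapmer_density_per_mb.
    """

    hap1_id: str
    hap2_id: str
    window_size: int
    table: pd.DataFrame

    def direction(self, haplotype: str) -> pd.DataFrame:
        return self.table[self.table["haplotype"] == haplotype].reset_index(drop=True)

    @property
    def median_shared_fraction(self) -> float:
        vals = self.table["shared_fraction"].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(np.median(vals)) if vals.size else float("nan")


def _direction_rows(
    haplotype: str,
    seq_id: str,
    length: int,
    scan: KmerScan,
    own_set: np.ndarray,
    partner_set: np.ndarray,
    hapmer_positions: np.ndarray,
    window_size: int,
) -> pd.DataFrame:
    n_win = max(1, -(-length // window_size))
    starts = np.arange(n_win, dtype=np.int64) * window_size
    ends = np.minimum(starts + window_size, length)
    widx = scan.hit_positions(scan.valid) // window_size
    n_valid = np.bincount(widx, minlength=n_win).astype(np.int64)
    # probe positions against the (small) set of own k-mers absent from the
    # partner instead of the whole partner set: same answer, cache-friendly
    absent = setdiff_sorted(own_set, partner_set)
    shared_mask = ~member_mask(scan.codes[scan.valid], hash_build(absent))
    n_shared = np.bincount(widx[shared_mask], minlength=n_win).astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, n_shared / np.maximum(n_valid, 1), np.nan)
    hap_counts = np.bincount(
        np.asarray(hapmer_positions, dtype=np.int64) // window_size, minlength=n_win
    ).astype(np.int64)
    spans = (ends - starts).astype(np.float64)
    return pd.DataFrame(
        {
            "haplotype": haplotype,
            "seq_id": seq_id,
            "start": starts,
            "end": ends,
            "n_valid": n_valid,
            "shared_fraction": frac,
            "hapmer_density_per_mb": hap_counts * 1e6 / spans,
        }
    )


def windowed_identity(
    pair: HomologPair,
    asm1: HaplotypeAssembly,
    asm2: HaplotypeAssembly,
    k: int,
    window_size: int = DEFAULT_WINDOW,
    mode: str = "full",
    scans1: dict[str, KmerScan] | None = None,
    scans2: dict[str, KmerScan] | None = None,
    sets1: dict[str, np.ndarray] | None = None,
    sets2: dict[str, np.ndarray] | None = None,
    hapmer_positions1: np.ndarray | None = None,
    hapmer_positions2: np.ndarray | None = None,
) -> IdentityTrack:
    """Both directions of the windowed identity proxy for one homolog pair.

    Optional precomputed scans/per-sequence k-mer sets/hap-mer positions
    let the pipeline avoid rescanning; when omitted they are recomputed
    (hap-mer densities then require the positions to be passed, otherwise
    they are reported as zero).
    """
    rec1 = asm1.get(pair.hap1_id)
    rec2 = asm2.get(pair.hap2_id)
    scan1 = scans1[rec1.id] if scans1 is not None else scan_sequence(rec1.bases, k, mode)
    scan2 = scans2[rec2.id] if scans2 is not None else scan_sequence(rec2.bases, k, mode)
    set1 = sets1[rec1.id] if sets1 is not None else sorted_unique(scan1.valid_codes)
    set2 = sets2[rec2.id] if sets2 is not None else sorted_unique(scan2.valid_codes)
    hp1 = hapmer_positions1 if hapmer_positions1 is not None else np.empty(0, dtype=np.int64)
    hp2 = hapmer_positions2 if hapmer_positions2 is not None else np.empty(0, dtype=np.int64)
    tab = pd.concat(
        [
            _direction_rows("hap1", rec1.id, rec1.length, scan1, set1, set2, hp1, window_size),
            _direction_rows("hap2", rec2.id, rec2.length, scan2, set2, set1, hp2, window_size),
        ],
        ignore_index=True,
    )
    return IdentityTrack(
        hap1_id=pair.hap1_id, hap2_id=pair.hap2_id, window_size=window_size, table=tab
    )


@dataclass
class Segment:
    hap1_id: str
    hap2_id: str
    haplotype: str
    seq_id: str
    start: int
    end: int
    kind: str  # sex_limited_candidate | PAR_candidate
    mean_shared_fraction: float


def segment_low_identity(
    track: IdentityTrack,
    drop_threshold: float = 0.9,
    min_windows: int = 2,
) -> list[Segment]:
    """Call candidate sex-limited regions (and flanking PAR candidates).

    A window is "low" when its shared fraction falls below
    ``drop_threshold`` times the pair's own median window shared fraction
    (all-N windows are excluded from both the median and segmentation).
    Maximal runs of at least ``min_windows`` low windows become sex-limited
    candidates; on directions carrying such a run, terminal non-low runs
    are reported as PAR candidates.
    """
    segments: list[Segment] = []
    for hap in ("hap1", "hap2"):
        rows = track.direction(hap)
        frac = rows["shared_fraction"].to_numpy(dtype=float)
        informative = ~np.isnan(frac)
        if not informative.any():
            continue
        med = float(np.median(frac[informative]))
        cut = drop_threshold * med
        low = informative & (frac < cut)
        low_runs = [(s, e) for s, e in true_runs(low) if e - s >= min_windows]
        for s, e in low_runs:
            seg_rows = rows.iloc[s:e]
            segments.append(
                Segment(
                    hap1_id=track.hap1_id,
                    hap2_id=track.hap2_id,
                    haplotype=hap,
                    seq_id=str(rows["seq_id"].iloc[0]),
                    start=int(seg_rows["start"].iloc[0]),
                    end=int(seg_rows["end"].iloc[-1]),
                    kind="sex_limited_candidate",
                    mean_shared_fraction=float(np.nanmean(seg_rows["shared_fraction"])),
                )
            )
        if low_runs:
            not_low = informative & ~low
            for s, e in true_runs(not_low):
                if s != 0 and e != len(rows):
                    continue  # only terminal high-identity runs are PAR candidates
                seg_rows = rows.iloc[s:e]
                segments.append(
                    Segment(
                        hap1_id=track.hap1_id,
                        hap2_id=track.hap2_id,
                        haplotype=hap,
                        seq_id=str(rows["seq_id"].iloc[0]),
                        start=int(seg_rows["start"].iloc[0]),
                        end=int(seg_rows["end"].iloc[-1]),
                        kind="PAR_candidate",
                        mean_shared_fraction=float(np.nanmean(seg_rows["shared_fraction"])),
                    )
                )
    return segments


def segments_table(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hap1_id": s.hap1_id,
                "hap2_id": s.hap2_id,
                "haplotype": s.haplotype,
                "seq_id": s.seq_id,
                "start": s.start,
                "end": s.end,
                "kind": s.kind,
                "mean_shared_fraction": s.mean_shared_fraction,
            }
            for s in segments
        ],
        columns=[
            "hap1_id", "hap2_id", "haplotype", "seq_id",
            "start", "end", "kind", "mean_shared_fraction",
        ],
    )


def write_identity_bed(tracks: list[IdentityTrack], path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\thaplotype\tshared_fraction\thapmer_density_per_mb\n")
        for tr in tracks:
            for _, r in tr.table.iterrows():
                sf = "NA" if np.isnan(r["shared_fraction"]) else f"{r['shared_fraction']:.6f}"
                fh.write(
                    f"{r['seq_id']}\t{int(r['start'])}\t{int(r['end'])}\t"
                    f"{r['haplotype']}\t{sf}\t{r['hapmer_density_per_mb']:.6f}\n"
                )
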