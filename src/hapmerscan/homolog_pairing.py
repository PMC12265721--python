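"""Pairing homologous sequences across the two haplotypes.

Pair-level evidence (identity tracks, convergence calls) needs to know
which hap1 sequence corresponds to which hap2 sequence.  Assemblies do not
guarantee matching names or order, so homologs are matched by shared-k-mer
containment: the fraction of one sequence's distinct canonical k-mers found
in the other.  Homologous chromosomes at realistic heterozygosity share the
vast majority of their k-mers, so reciprocal-best containment with a
moderate floor recovers the 1:1 correspondence even when a sex-limited
region diverges strongly inside one pair.  This is a k-mer re-design of
what whole-genome aligners provide, not a wrapper around one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import intersect_count_sorted, sorted_unique
from .kmer_engine import KmerScan, scan_sequence
from .sequence_io import HaplotypeAssembly


@dataclass
class HomologPair:
    hap1_id: str
    hap2_id: str
    containment_1in2: float  # |k-mers(hap1 seq) ∩ k-mers(hap2 seq)| / |k-mers(hap1 seq)|
    containment_2in1: float
    reciprocal_best: bool = True


def sequence_kmer_sets(
    assembly: HaplotypeAssembly,
    k: int,
    mode: str = "full",
    scans: dict[str, KmerScan] | None = None,
) -> dict[str, np.ndarray]:
    """Per-sequence distinct canonical k-mer sets (sorted uint64 arrays)."""
    out: dict[str, np.ndarray] = {}
    for rec in assembly:
        scan = scans[rec.id] if scans is not None else scan_sequence(rec.bases, k, mode)
        out[rec.id] = sorted_unique(scan.valid_codes, in_place=True)
    return out


def containment(set_a: np.ndarray, set_b: np.ndarray) -> float:
    """|A ∩ B| / |A| on sorted unique code arrays; 0.0 when A is empty."""
    if set_a.size == 0:
        return 0.0
    return intersect_count_sorted(set_a, set_b) / set_a.size


def _intersection_matrix(
    sets1: dict[str, np.ndarray], sets2: dict[str, np.ndarray]
) -> np.ndarray:
    """Distinct-shared-k-mer counts for every (hap1 seq, hap2 seq) pair."""
    inter = np.zeros((len(sets1), len(sets2)), dtype=np.int64)
    for i, a in enumerate(sets1.values()):
        for j, b in enumerate(sets2.values()):
            if a.size and b.size:
                inter[i, j] = intersect_count_sorted(a, b)
    return inter


def pair_homologs(
    asm1: HaplotypeAssembly,
    asm2: HaplotypeAssembly,
    k: int,
    min_containment: float = 0.5,
    mode: str = "full",
    sets1: dict[str, np.ndarray] | None = None,
    sets2: dict[str, np.ndarray] | None = None,
) -> tuple[list[HomologPair], list[tuple[str, str]]]:
    """Reciprocal-best containment matching of hap1 vs hap2 sequences.

    A pair is emitted iff it is reciprocal-best and
    ``max(containment_1in2, containment_2in1) >= min_containment``.
    Ties break by higher opposite-direction containment, then longer
    partner sequence, then lexicographic id.  Returns (pairs, unpaired)
    where unpaired lists (haplotype, seq_id).
    """
    if len(asm1) == 0 or len(asm2) == 0:
        raise ValueError("both assemblies must be non-empty")
    if sets1 is None:
        sets1 = sequence_kmer_sets(asm1, k, mode)
    if sets2 is None:
        sets2 = sequence_kmer_sets(asm2, k, mode)
    ids1 = [r.id for r in asm1]
    ids2 = [r.id for r in asm2]
    len2 = {r.id: r.length for r in asm2}
    len1 = {r.id: r.length for r in asm1}
    sizes1 = np.array([max(sets1[i].size, 1) for i in ids1], dtype=np.float64)
    sizes2 = np.array([max(sets2[i].size, 1) for i in ids2], dtype=np.float64)

    inter = _intersection_matrix(
        {i: sets1[i] for i in ids1}, {i: sets2[i] for i in ids2}
    ).astype(np.float64)
    c12 = inter / sizes1[:, None]  # containment of hap1 seq i within hap2 seq j
    c21 = inter / sizes2[None, :]

    def best_j(i: int) -> int:
        key = [(c12[i, j], c21[i, j], len2[ids2[j]], -ord_rank(ids2[j])) for j in range(len(ids2))]
        return max(range(len(ids2)), key=lambda j: key[j])

    def best_i(j: int) -> int:
        key = [(c21[i, j], c12[i, j], len1[ids1[i]], -ord_rank(ids1[i])) for i in range(len(ids1))]
        return max(range(len(ids1)), key=lambda i: key[i])

    # lexicographically smaller id wins ties -> rank by sorted position
    all_ids = sorted(set(ids1) | set(ids2))
    rank = {s: r for r, s in enumerate(all_ids)}

    def ord_rank(s: str) -> int:
        return rank[s]

    pairs: list[HomologPair] = []
    paired1: set[str] = set()
    paired2: set[str] = set()
    for i, sid1 in enumerate(ids1):
        j = best_j(i)
        if best_i(j) != i:
            continue
        cin2, cin1 = float(c12[i, j]), float(c21[i, j])
        if max(cin2, cin1) < min_containment:
            continue
        pairs.append(
            HomologPair(
                hap1_id=sid1,
                hap2_id=ids2[j],
                containment_1in2=cin2,
                containment_2in1=cin1,
            )
        )
        paired1.add(sid1)
        paired2.add(ids2[j])
    unpaired = [("hap1", s) for s in ids1 if s not in paired1]
    unpaired += [("hap2", s) for s in ids2 if s not in paired2]
    return pairs, unpaired


def pairs_table(pairs: list[HomologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "hap1_id": p.hap1_id,
                "hap2_id": p.hap2_id,
                "containment_1in2": p.containment_1in2,
                "containment_2in1": p.containment_2in1,
                "reciprocal_best": p.reciprocal_best,
            }
            for p in pairs
        ],
        columns=["hap1_id", "hap2_id", "containment_1in2", "containment_2in1", "reciprocal_best"],
    )


def write_pairs(pairs: list[HomologPair], unpaired: list[tuple[str, str]],
                pairs_path: str | Path, unpaired_path: str | Path) -> None:
    pairs_table(pairs).to_csv(pairs_path, sep="\t", index=False, float_format="%.6f")
    pd.DataFrame(unpaired, columns=["haplotype", "seq_id"]).to_csv(
        unpaired_path, sep="\t", index=False
    )
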