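"""Synthetic diploid assemblies with known truth.

The generator emulates the input the workflow consumes in the wild: two
haplotype FASTAs of one diploid individual.  hap2 is derived from hap1 by
per-base substitutions and short indels at an autosomal heterozygosity
rate; one optional sex-chromosome pair carries a central sex-limited
region diverged at an elevated rate, optionally a pseudoautosomal region
(PAR) at one distal tip kept at background divergence, optional Y/W
shortening and tandem-repeat expansion inside the sex-limited region, and
an optional "dearth" mode where one homogametic pair has its
heterozygosity divided by a constant factor.  A machine-readable truth
file records the homolog pairing, the sex pair, and every interval in
final (post-indel) coordinates of both haplotypes.

Divergence is applied asymmetrically (hap2 mutated from hap1) rather than
from a shared ancestor: for hap-mer purposes at these rates the two
constructions are equivalent, and one-sided mutation keeps coordinate
bookkeeping exact.  Defaults are illustrative desk-scale settings — 10
autosome pairs with log-spread lengths of 0.5–3 Mb at 0.2% SNP
heterozygosity, and a 10 Mb sex pair with 40% of its length diverged at
2% — not measurements of any particular organism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .sequence_io import HaplotypeAssembly, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
REPEAT_UNIT = "TTAGGGTTAGGG"  # fixed 12-mer tandem unit for Y/W repeat expansion
MIN_SEQ_LEN = 280  # 10 * default k

SEX_SYSTEMS = ("none", "XY", "ZW", "dearth_homogametic")


@dataclass
class SimConfig:
    seed: int = 0
    n_autosome_pairs: int = 10
    autosome_lengths: Optional[list[int]] = None  # default: geomspace 0.5–3 Mb
    het_snp_rate: float = 0.002
    het_indel_rate: float = 0.0002
    indel_mean_length: float = 2.0
    sex_system: str = "none"
    sex_length: int = 10_000_000
    sex_limited_fraction: float = 0.4
    sex_limited_divergence: float = 0.02
    par_fraction: float = 0.0
    y_truncation_fraction: float = 0.0
    repeat_expansion_bp: int = 0
    dearth_factor: float = 10.0

    def validate(self) -> None:
        for name in ("het_snp_rate", "het_indel_rate", "sex_limited_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.25):
                raise ValueError(f"{name} must be in [0, 0.25], got {v}")
        if self.sex_system not in SEX_SYSTEMS:
            raise ValueError(f"sex_system must be one of {SEX_SYSTEMS}")
        if not (0.0 < self.sex_limited_fraction < 1.0):
            raise ValueError("sex_limited_fraction must be in (0, 1)")
        if not (0.0 <= self.par_fraction < 1.0):
            raise ValueError("par_fraction must be in [0, 1)")
        if not (0.0 <= self.y_truncation_fraction < 1.0):
            raise ValueError("y_truncation_fraction must be in [0, 1)")
        if self.dearth_factor < 1.0:
            raise ValueError("dearth_factor must be >= 1")
        if self.repeat_expansion_bp < 0:
            raise ValueError("repeat_expansion_bp must be >= 0")
        if self.indel_mean_length < 1.0:
            raise ValueError("indel_mean_length must be >= 1")
        if self.n_autosome_pairs < 0:
            raise ValueError("n_autosome_pairs must be >= 0")
        if self.sex_limited_fraction / 2 + self.par_fraction > 0.5:
            raise ValueError("centred sex-limited interval would overlap the PAR")
        for L in self.resolved_autosome_lengths():
            if L < MIN_SEQ_LEN:
                raise ValueError(f"autosome length {L} < {MIN_SEQ_LEN} bp")
        if self.sex_system != "none" and self.sex_length < MIN_SEQ_LEN:
            raise ValueError(f"sex_length {self.sex_length} < {MIN_SEQ_LEN} bp")

    def resolved_autosome_lengths(self) -> list[int]:
        if self.autosome_lengths is not None:
            return [int(v) for v in self.autosome_lengths]
        if self.n_autosome_pairs == 0:
            return []
        return [
            int(round(v))
            for v in np.geomspace(500_000, 3_000_000, self.n_autosome_pairs)
        ]


@dataclass
class TruthSet:
    """Ground truth of one simulated diploid, in final coordinates."""

    sex_system: str
    pairing: list[tuple[str, str]]
    sex_pair: Optional[tuple[str, str]] = None
    sex_limited: Optional[dict[str, tuple[int, int]]] = None  # per haplotype, 0-based half-open
    par: Optional[dict[str, tuple[int, int]]] = None
    mutation_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def _draw_positions(rng: np.random.Generator, start: int, end: int, rate: float) -> np.ndarray:
    if rate <= 0.0 or end <= start:
        return np.empty(0, dtype=np.int64)
    mask = rng.random(end - start) < rate
    return start + np.flatnonzero(mask).astype(np.int64)


def _derive_hap2(
    anc: np.ndarray,
    intervals: list[tuple[int, int, float, float]],
    rng: np.random.Generator,
    indel_mean: float = 2.0,
) -> tuple[np.ndarray, Callable[[int], int], dict[str, int]]:
    """Mutate hap1 bases into hap2 over rate intervals.

    Returns the mutated code array, a function mapping hap1 coordinates to
    hap2 coordinates (exact through all applied indels), and realized
    event counts.
    """
    L = anc.size
    seq2 = anc.copy()
    n_sub = 0
    for s, e, snp_rate, _ in intervals:
        idx = _draw_positions(rng, s, e, snp_rate)
        if idx.size:
            seq2[idx] = (seq2[idx] + rng.integers(1, 4, idx.size, dtype=np.uint8)) % 4
        n_sub += int(idx.size)

    # indel events: (pos, kind, length, inserted bases)
    events = []
    for s, e, _, indel_rate in intervals:
        for pos in _draw_positions(rng, s, e, indel_rate):
            length = int(rng.geometric(1.0 / indel_mean))  # geometric lengths, mean indel_mean
            if rng.random() < 0.5:
                events.append((int(pos), "ins", length, rng.integers(0, 4, length, dtype=np.uint8)))
            else:
                events.append((int(pos), "del", length, None))
    events.sort(key=lambda ev: ev[0])

    pieces = []
    applied = []  # (orig pos, kind, length)
    cur = 0
    n_ins = n_del = 0
    for pos, kind, length, ins in events:
        if pos < cur or pos >= L:
            continue  # overlaps a previous deletion
        pieces.append(seq2[cur:pos])
        if kind == "del":
            length = min(length, L - pos)
            cur = pos + length
            n_del += 1
        else:
            pieces.append(ins)
            cur = pos
            n_ins += 1
        applied.append((pos, kind, length))
    pieces.append(seq2[cur:])
    hap2 = np.concatenate(pieces) if len(pieces) > 1 else pieces[0].copy()

    def map_coord(x: int) -> int:
        """hap1 coordinate -> hap2 coordinate (deletion interiors snap to their start)."""
        shift = 0
        for pos, kind, length in applied:
            if pos > x:
                break
            if kind == "ins":
                shift += length
            else:
                shift -= min(length, x - pos)
        return x + shift

    counts = {"substitutions": n_sub, "insertions": n_ins, "deletions": n_del}
    return hap2, map_coord, counts


def _codes_to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _str_to_codes(s: str) -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def simulate_diploid(config: SimConfig) -> tuple[HaplotypeAssembly, HaplotypeAssembly, TruthSet]:
    """Generate paired haplotype assemblies plus their truth set.

    Byte-deterministic for a fixed (seed, config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bg = (config.het_snp_rate, config.het_indel_rate)

    names: list[str] = []
    recs1: list[SequenceRecord] = []
    recs2: list[SequenceRecord] = []
    truth = TruthSet(sex_system=config.sex_system, pairing=[])

    def add_pair(name: str, anc: np.ndarray, intervals) -> Callable[[int], int]:
        id1, id2 = f"{name}_h1", f"{name}_h2"
        hap2, map_coord, counts = _derive_hap2(anc, intervals, rng, config.indel_mean_length)
        recs1.append(SequenceRecord(id=id1, bases=_codes_to_str(anc)))
        recs2.append(SequenceRecord(id=id2, bases=_codes_to_str(hap2)))
        names.append(name)
        truth.pairing.append((id1, id2))
        truth.mutation_counts[id2] = counts
        return map_coord

    for i, L in enumerate(config.resolved_autosome_lengths(), start=1):
        anc = rng.integers(0, 4, L, dtype=np.uint8)
        add_pair(f"chr{i:02d}", anc, [(0, L, *bg)])

    if config.sex_system != "none":
        L = int(config.sex_length)
        anc = rng.integers(0, 4, L, dtype=np.uint8)
        name = f"chr{len(names) + 1:02d}"
        if config.sex_system == "dearth_homogametic":
            df = config.dearth_factor
            map_coord = add_pair(name, anc, [(0, L, bg[0] / df, bg[1] / df)])
            truth.sex_pair = truth.pairing[-1]
        else:
            sl_len = int(round(config.sex_limited_fraction * L))
            sl_s = (L - sl_len) // 2
            sl_e = sl_s + sl_len
            par_len = int(round(config.par_fraction * L))
            intervals = [
                (0, sl_s, *bg),
                (sl_s, sl_e, config.sex_limited_divergence, bg[1]),
                (sl_e, L, *bg),
            ]
            map_coord = add_pair(name, anc, intervals)
            truth.sex_pair = truth.pairing[-1]
            sl2_s, sl2_e = map_coord(sl_s), map_coord(sl_e)

            # Y/W shaping happens on hap2 after divergence
            hap2_codes = _str_to_codes(recs2[-1].bases)
            if config.y_truncation_fraction > 0:
                dlen = int(round(config.y_truncation_fraction * (sl2_e - sl2_s)))
                c = (sl2_s + sl2_e) // 2 - dlen // 2
                hap2_codes = np.concatenate([hap2_codes[:c], hap2_codes[c + dlen:]])
                sl2_e -= dlen
            if config.repeat_expansion_bp > 0:
                rep = _str_to_codes(
                    (REPEAT_UNIT * (config.repeat_expansion_bp // len(REPEAT_UNIT) + 1))[
                        : config.repeat_expansion_bp
                    ]
                )
                c = (sl2_s + sl2_e) // 2
                hap2_codes = np.concatenate([hap2_codes[:c], rep, hap2_codes[c:]])
                sl2_e += rep.size
            recs2[-1] = SequenceRecord(id=recs2[-1].id, bases=_codes_to_str(hap2_codes))

            truth.sex_limited = {"hap1": (sl_s, sl_e), "hap2": (sl2_s, sl2_e)}
            if par_len > 0:
                truth.par = {
                    "hap1": (L - par_len, L),
                    "hap2": (map_coord(L - par_len), len(recs2[-1].bases)),
                }

    if not recs1:
        raise ValueError("config produces an empty genome")

    # emit hap2 in a shuffled order so pairing is non-trivial
    perm = rng.permutation(len(recs2))
    recs2 = [recs2[i] for i in perm]

    asm1 = HaplotypeAssembly(label="hap1", records=recs1)
    asm2 = HaplotypeAssembly(label="hap2", records=recs2)
    return asm1, asm2, truth


def write_truth(truth: TruthSet, path: str | Path) -> None:
    obj = asdict(truth)
    with open(path, "wt") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> TruthSet:
    with open(path) as fh:
        obj = json.load(fh)
    required = {"sex_system", "pairing"}
    missing = required - obj.keys()
    if missing:
        raise ValueError(f"truth file missing fields: {sorted(missing)}")
    if obj["sex_system"] not in SEX_SYSTEMS:
        raise ValueError(f"invalid sex_system {obj['sex_system']!r}")

    def _interval(v):
        if v is None:
            return None
        return {k: (int(a), int(b)) for k, (a, b) in v.items()}

    return TruthSet(
        sex_system=obj["sex_system"],
        pairing=[(a, b) for a, b in obj["pairing"]],
        sex_pair=tuple(obj["sex_pair"]) if obj.get("sex_pair") else None,
        sex_limited=_interval(obj.get("sex_limited")),
        par=_interval(obj.get("par")),
        mutation_counts={
            k: {kk: int(vv) for kk, vv in v.items()}
            for k, v in obj.get("mutation_counts", {}).items()
        },
    )
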