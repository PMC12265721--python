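"""FASTA input/output for haplotype assemblies.

A haplotype-resolved diploid assembly arrives as two FASTA files, one per
haplotype.  This module owns parsing, base normalisation and the minimum
length filter applied to contig-level inputs, and fixes the coordinate
convention used everywhere downstream: 0-based, half-open.

Normalisation rules: bases are uppercased (soft-masking carries no meaning
for haplotype uniqueness), U is mapped to T, and every other IUPAC
ambiguity code is mapped to N.  k-mer windows spanning an N are skipped
downstream, so ambiguous bases simply create small gaps in the k-mer
tracks rather than hard errors.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

_IUPAC = "ACGTUWSMKRYBDHVN"
# translation table: ACGT/N kept, U->T, other IUPAC codes -> N, case folded;
# anything outside the IUPAC alphabet translates to \x00 so it can be reported
_TABLE = bytearray(256)
for _c in _IUPAC:
    _t = {"U": "T"}.get(_c, _c if _c in "ACGTN" else "N")
    _TABLE[ord(_c)] = ord(_t)
    _TABLE[ord(_c.lower())] = ord(_t)
_TABLE = bytes(_TABLE)


def normalize_bases(raw: str, *, context: str = "") -> str:
    """Uppercase, U->T, non-ACGT IUPAC codes -> N; reject anything else."""
    out = raw.encode("ascii", errors="replace").translate(_TABLE)
    if b"\x00" in out:
        bad = raw[out.index(b"\x00")]
        raise ValueError(f"invalid sequence character {bad!r}{context}")
    return out.decode("ascii")


@dataclass
class SequenceRecord:
    """One named sequence of an assembly (normalised ACGTN, uppercase)."""

    id: str
    bases: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass
class HaplotypeAssembly:
    """Ordered sequences of one haplotype, labelled hap1 or hap2."""

    label: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("hap1", "hap2"):
            raise ValueError(f"label must be 'hap1' or 'hap2', got {self.label!r}")
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r} in {self.label}")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, label: str) -> HaplotypeAssembly:
    """Parse a (possibly gzip-compressed) FASTA file into an assembly.

    Raises ``ValueError`` on an empty file, a duplicate record id, or
    content that is not FASTA (reported with its line number).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_desc = ""
    chunks: list[str] = []

    def _flush() -> None:
        if cur_id is None:
            return
        bases = normalize_bases("".join(chunks), context=f" in record {cur_id!r}")
        if not bases:
            raise ValueError(f"record {cur_id!r} has no sequence")
        records.append(SequenceRecord(id=cur_id, bases=bases, description=cur_desc))

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}: empty FASTA header at line {lineno}")
                parts = header.split(None, 1)
                cur_id = parts[0]
                cur_desc = parts[1] if len(parts) > 1 else ""
                if cur_id in seen:
                    raise ValueError(f"{path}: duplicate sequence id {cur_id!r}")
                seen.add(cur_id)
                chunks = []
            else:
                if cur_id is None:
                    raise ValueError(
                        f"{path}: not FASTA — sequence before header at line {lineno}"
                    )
                chunks.append(line)
    _flush()
    if not records:
        raise ValueError(f"{path}: no sequences")
    return HaplotypeAssembly(label=label, records=records)


def write_fasta(assembly: HaplotypeAssembly, path: str | Path, line_width: int = 60) -> None:
    """Write records in order, wrapping bases at ``line_width`` columns."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rec in assembly:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, rec.length, line_width):
                fh.write(rec.bases[i : i + line_width] + "\n")


def filter_min_length(assembly: HaplotypeAssembly, min_len: int = 1_000_000) -> HaplotypeAssembly:
    """Drop sequences shorter than ``min_len`` bp (keep if length >= min_len).

    Contig-level assemblies carry short 'shrapnel' that adds regression
    noise without information; the default removes everything under 1 Mb.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    kept = [r for r in assembly.records if r.length >= min_len]
    if not kept:
        raise ValueError(f"all sequences shorter than min_len={min_len}")
    n_removed = len(assembly.records) - len(kept)
    bp_removed = assembly.total_length - sum(r.length for r in kept)
    logger.info(
        "%s: length filter (>= %d bp) removed %d sequence(s), %d bp",
        assembly.label, min_len, n_removed, bp_removed,
    )
    return HaplotypeAssembly(label=assembly.label, records=kept)


def assembly_summary(assemblies: Iterable[HaplotypeAssembly]) -> pd.DataFrame:
    """Per-sequence length table: haplotype, seq_id, length_bp."""
    rows = [
        {"haplotype": asm.label, "seq_id": r.id, "length_bp": r.length}
        for asm in assemblies
        for r in asm
    ]
    return pd.DataFrame(rows, columns=["haplotype", "seq_id", "length_bp"])
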