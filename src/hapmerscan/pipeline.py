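"""End-to-end orchestration: read → count → negate → locate → window →
pair → identity → outlier calls → report bundle.

Each sequence is scanned for canonical k-mers exactly once; the resulting
per-sequence code arrays feed k-mer counting, hap-mer location, homolog
pairing and the identity tracks, so a default desk-scale genome runs in
seconds.  All tabular outputs are written with fixed column order and
fixed float formatting, making repeated runs byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import hapmer_core, homolog_pairing, identity_track, kmer_engine, outlier_stats
from ._kernels import setdiff_sorted, sorted_unique
from .sequence_io import HaplotypeAssembly, assembly_summary, filter_min_length, read_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    hap1_path: str = ""
    hap2_path: str = ""
    k: int = kmer_engine.DEFAULT_K
    window_size: int = hapmer_core.DEFAULT_WINDOW
    min_len: int = 1_000_000
    apply_min_len: bool = True
    mode: str = "full"
    t_threshold: float = outlier_stats.T_THRESHOLD
    min_containment: float = 0.5
    consecutive_windows: int = 3
    segment_drop_threshold: float = 0.9
    segment_min_windows: int = 2
    dearth_identity_ratio: float = 0.5
    outdir: str = "hapmerscan_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class ReportBundle:
    outdir: Path
    results: pd.DataFrame
    pairs: pd.DataFrame
    unpaired: pd.DataFrame
    outliers: pd.DataFrame
    pair_calls: pd.DataFrame
    segments: pd.DataFrame
    window_tracks: dict = field(default_factory=dict)
    identity_tracks: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def candidate_pairs(self) -> pd.DataFrame:
        return self.pair_calls[self.pair_calls["pair_flag"] != "none"]


def _scan_assembly(asm: HaplotypeAssembly, k: int, mode: str):
    return {rec.id: kmer_engine.scan_sequence(rec.bases, k, mode) for rec in asm}


def run_pipeline(
    config: RunConfig,
    assemblies: tuple[HaplotypeAssembly, HaplotypeAssembly] | None = None,
    write: bool = True,
) -> ReportBundle:
    """Execute the full workflow.

    ``assemblies`` short-circuits FASTA reading (used by the simulator
    round-trips and the test-suite); with ``write=False`` no files are
    produced and the bundle is returned in memory only.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("[%s] %.1fs", name, time.time() - t0)

    try:
        if assemblies is None:
            asm1 = read_fasta(config.hap1_path, "hap1")
            asm2 = read_fasta(config.hap2_path, "hap2")
        else:
            asm1, asm2 = assemblies
        if config.apply_min_len and config.min_len > 0:
            asm1 = filter_min_length(asm1, config.min_len)
            asm2 = filter_min_length(asm2, config.min_len)
        stage("read")

        k, mode = config.k, config.mode
        scans1 = _scan_assembly(asm1, k, mode)
        scans2 = _scan_assembly(asm2, k, mode)
        stage("scan")

        # per-sequence distinct sets feed pairing, identity AND the
        # assembly-level negation, so build them first and only once
        sets1 = homolog_pairing.sequence_kmer_sets(asm1, k, mode, scans=scans1)
        sets2 = homolog_pairing.sequence_kmer_sets(asm2, k, mode, scans=scans2)
        distinct1 = sorted_unique(np.concatenate(list(sets1.values())), in_place=True)
        distinct2 = sorted_unique(np.concatenate(list(sets2.values())), in_place=True)
        kmer_stats = {
            "hap1": {
                "distinct": int(distinct1.size),
                "occurrences": sum(int(s.valid.sum()) for s in scans1.values()),
            },
            "hap2": {
                "distinct": int(distinct2.size),
                "occurrences": sum(int(s.valid.sum()) for s in scans2.values()),
            },
        }
        logger.info("k-mers: hap1 %s; hap2 %s", kmer_stats["hap1"], kmer_stats["hap2"])
        hs1 = hapmer_core.HapmerSet(
            haplotype="hap1", k=k, codes=setdiff_sorted(distinct1, distinct2)
        )
        hs2 = hapmer_core.HapmerSet(
            haplotype="hap2", k=k, codes=setdiff_sorted(distinct2, distinct1)
        )
        del distinct1, distinct2
        logger.info("hap-mers: hap1 %d, hap2 %d distinct", hs1.n, hs2.n)
        stage("negate")

        occ1 = hapmer_core.locate_hapmers(asm1, hs1, mode, scans=scans1)
        occ2 = hapmer_core.locate_hapmers(asm2, hs2, mode, scans=scans2)
        prof1 = hapmer_core.build_profile(asm1, occ1)
        prof2 = hapmer_core.build_profile(asm2, occ2)
        tracks = {}
        for asm, occ, hap in ((asm1, occ1, "hap1"), (asm2, occ2, "hap2")):
            for rec in asm:
                tracks[(hap, rec.id)] = hapmer_core.build_window_track(
                    rec, occ.positions[rec.id], config.window_size, k=k
                )
        stage("profile")

        pairs, unpaired = homolog_pairing.pair_homologs(
            asm1, asm2, k, config.min_containment, mode, sets1=sets1, sets2=sets2
        )
        logger.info("pairs: %d matched, %d unpaired", len(pairs), len(unpaired))
        stage("pair")

        itracks = [
            identity_track.windowed_identity(
                p, asm1, asm2, k, config.window_size, mode,
                scans1=scans1, scans2=scans2, sets1=sets1, sets2=sets2,
                hapmer_positions1=occ1.positions[p.hap1_id],
                hapmer_positions2=occ2.positions[p.hap2_id],
            )
            for p in pairs
        ]
        del scans1, scans2, sets1, sets2
        identity_medians = {
            (tr.hap1_id, tr.hap2_id): tr.median_shared_fraction for tr in itracks
        }
        segs: list[identity_track.Segment] = []
        for tr in itracks:
            segs.extend(
                identity_track.segment_low_identity(
                    tr, config.segment_drop_threshold, config.segment_min_windows
                )
            )
        stage("identity")

        results_rows = []
        for hap, prof in (("hap1", prof1), ("hap2", prof2)):
            t = prof.table.copy()
            t.insert(0, "haplotype", hap)
            results_rows.append(t)
        seq_table = pd.concat(results_rows, ignore_index=True)

        flagged, fit = outlier_stats.flag_regression_outliers(
            seq_table, t_threshold=config.t_threshold
        )
        flagged, box_summaries = outlier_stats.boxplot_flags(flagged)
        if pairs:
            pair_calls = outlier_stats.summarize_pairs(
                pairs, flagged, tracks, identity_medians, config.consecutive_windows,
                dearth_identity_ratio=config.dearth_identity_ratio,
            )
        else:
            logger.warning("no homolog pairs matched; skipping pair-level calls")
            pair_calls = pd.DataFrame(
                columns=[
                    "hap1_id", "hap2_id", "pair_flag", "n_flagged_members",
                    "max_consecutive_high_windows", "window_upper_fence",
                    "median_shared_fraction",
                ]
            )
        stage("outliers")

        summary = {
            "version": __version__,
            "config": dataclasses.asdict(config),
            "n_sequences": {"hap1": len(asm1), "hap2": len(asm2)},
            "total_length": {"hap1": asm1.total_length, "hap2": asm2.total_length},
            "kmers": kmer_stats,
            "hapmers": {
                "hap1": {"distinct": hs1.n, "occurrences": occ1.total},
                "hap2": {"distinct": hs2.n, "occurrences": occ2.total},
            },
            "fit": {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
                "residual_sd": fit.residual_sd,
            },
            "boxplot": {
                s.haplotype: dataclasses.asdict(s) for s in box_summaries
            },
            "flags": {
                "regression_excess": sorted(
                    flagged.loc[flagged["regression_flag"] == "excess", "seq_id"]
                ),
                "regression_dearth": sorted(
                    flagged.loc[flagged["regression_flag"] == "dearth", "seq_id"]
                ),
                "boxplot_high": sorted(
                    flagged.loc[flagged["boxplot_flag"] == "high", "seq_id"]
                ),
                "boxplot_low": sorted(
                    flagged.loc[flagged["boxplot_flag"] == "low", "seq_id"]
                ),
            },
            "pair_calls": pair_calls[pair_calls["pair_flag"] != "none"][
                ["hap1_id", "hap2_id", "pair_flag"]
            ].to_dict(orient="records"),
            "n_pairs": len(pairs),
            "n_unpaired": len(unpaired),
        }

        bundle = ReportBundle(
            outdir=outdir,
            results=seq_table,
            pairs=homolog_pairing.pairs_table(pairs),
            unpaired=pd.DataFrame(unpaired, columns=["haplotype", "seq_id"]),
            outliers=flagged,
            pair_calls=pair_calls,
            segments=identity_track.segments_table(segs),
            window_tracks=tracks,
            identity_tracks=itracks,
            summary=summary,
        )
        if write:
            _write_bundle(bundle, [asm1, asm2], pairs, unpaired)
        stage("done")
        return bundle
    except Exception as exc:  # annotate failures with the pipeline context
        logger.error("pipeline failed: %s", exc)
        raise


def _write_bundle(bundle: ReportBundle, assemblies, pairs, unpaired) -> None:
    out = bundle.outdir
    assembly_summary(assemblies).to_csv(out / "assembly_summary.tsv", sep="\t", index=False)
    bundle.results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.6f")
    hapmer_core.write_windows_bed(bundle.window_tracks, out / "windows.bed")
    homolog_pairing.write_pairs(pairs, unpaired, out / "pairs.tsv", out / "unpaired.tsv")
    bundle.outliers.to_csv(out / "outliers.tsv", sep="\t", index=False, float_format="%.6f")
    bundle.pair_calls.to_csv(out / "pair_calls.tsv", sep="\t", index=False, float_format="%.6f")
    identity_track.write_identity_bed(bundle.identity_tracks, out / "identity.bed")
    bundle.segments.to_csv(out / "segments.tsv", sep="\t", index=False, float_format="%.6f")
    with open(out / "summary.json", "wt") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
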