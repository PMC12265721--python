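"""Static plots of a finished run: dot plot, density boxplot, mirror plots.

Generic matplotlib renderings of the numbers already written to the TSV
outputs; anything fancier can be rebuilt from those tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _load(outdir: Path, name: str) -> pd.DataFrame:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(f"missing bundle member: {path}")
    return pd.read_csv(path, sep="\t")


def make_plots(outdir: str | Path, plot_dir: str | Path | None = None) -> list[Path]:
    """Render dot plot, boxplot, and one mirror plot per pair from a bundle dir."""
    outdir = Path(outdir)
    plot_dir = Path(plot_dir) if plot_dir is not None else outdir
    plot_dir.mkdir(parents=True, exist_ok=True)
    outliers = _load(outdir, "outliers.tsv")
    ident = pd.read_csv(outdir / "identity.bed", sep="\t", na_values="NA")
    ident.columns = [c.lstrip("#") for c in ident.columns]
    pair_calls = _load(outdir, "pair_calls.tsv")
    written: list[Path] = []

    # dot plot: hap-mer occurrences ~ length, flagged points labelled
    fig, ax = plt.subplots(figsize=(6, 5))
    for hap, marker in (("hap1", "o"), ("hap2", "s")):
        sub = outliers[outliers["haplotype"] == hap]
        ax.scatter(sub["length_bp"] / 1e6, sub["hapmer_occurrences"], s=25,
                   marker=marker, label=hap, alpha=0.7)
    flagged = outliers[(outliers["regression_flag"] != "none")
                       | (outliers["boxplot_flag"] != "none")]
    for _, r in flagged.iterrows():
        ax.annotate(r["seq_id"], (r["length_bp"] / 1e6, r["hapmer_occurrences"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    x = outliers["length_bp"].to_numpy(dtype=float)
    y = outliers["hapmer_occurrences"].to_numpy(dtype=float)
    if np.ptp(x) > 0 and len(x) >= 2:
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs / 1e6, a + b * xs, "k--", lw=1, label="OLS fit")
    ax.set_xlabel("sequence length (Mb)")
    ax.set_ylabel("hap-mer occurrences")
    ax.legend()
    fig.tight_layout()
    p = plot_dir / "dotplot.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # per-haplotype density boxplot
    fig, ax = plt.subplots(figsize=(4, 5))
    data = [outliers.loc[outliers["haplotype"] == h, "density_per_mb"] for h in ("hap1", "hap2")]
    ax.boxplot(data, tick_labels=["hap1", "hap2"], whis=1.5)
    ax.set_ylabel("hap-mer density (per Mb)")
    fig.tight_layout()
    p = plot_dir / "density_boxplot.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # mirror plot per pair: hap1 window densities up, hap2 down, identity overlay
    for _, pr in pair_calls.iterrows():
        fig, ax = plt.subplots(figsize=(7, 4))
        ax2 = ax.twinx()
        for hap, sid, sign in (("hap1", pr["hap1_id"], 1), ("hap2", pr["hap2_id"], -1)):
            sub = ident[(ident["haplotype"] == hap) & (ident["chrom"] == sid)]
            if sub.empty:
                continue
            mid = (sub["start"] + sub["end"]) / 2e6
            ax.bar(mid, sign * sub["hapmer_density_per_mb"],
                   width=(sub["end"] - sub["start"]) / 1e6, alpha=0.6,
                   label=f"{hap} density")
            ax2.plot(mid, sub["shared_fraction"], lw=1.2,
                     ls="-" if sign > 0 else "--", color="black")
            if sign > 0:
                ax.set_xlim(0, sub["end"].max() / 1e6)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xlabel("position (Mb)")
        ax.set_ylabel("hap-mer density per Mb (hap1 up / hap2 down)")
        ax2.set_ylabel("shared k-mer fraction")
        ax2.set_ylim(0, 1.05)
        ax.set_title(f"{pr['hap1_id']} / {pr['hap2_id']} [{pr['pair_flag']}]")
        fig.tight_layout()
        p = plot_dir / f"mirror_{pr['hap1_id']}_{pr['hap2_id']}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
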