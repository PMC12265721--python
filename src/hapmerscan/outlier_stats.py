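"""Autosomal background model and outlier detection.

Across a diploid genome, total hap-mer count per sequence grows close to
linearly with sequence length: heterozygous differences accumulate at a
roughly uniform per-bp rate along recombining chromosomes.  Sequences that
carry a non-recombining sex-limited region sit far above that line
(an excess of hap-mers), while an old, diversity-depleted homogametic sex
pair can sit far below it (a dearth).  Misassembled or misphased regions
produce the same kinds of deviation, which is why every call here is a
candidate for scrutiny rather than a significance claim.

Three explicit evidence layers are computed:

* an ordinary least squares fit of hap-mer occurrences on sequence length
  (both haplotypes pooled), with externally studentized residuals flagged
  at |t| > 3 and one refit round excluding the first-pass flags so a large
  sex chromosome cannot mask itself;
* Tukey fences (Q1 - 1.5*IQR, Q3 + 1.5*IQR) on per-sequence hap-mer
  density, per haplotype;
* a windowed convergence rule at pair level: an excess call needs a flagged
  member plus at least ``m`` consecutive windows above the autosomal
  per-window upper fence; a dearth call needs a low-flagged member plus
  pair identity clearly above the autosomal background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from ._util import max_consecutive_true

logger = logging.getLogger(__name__)

T_THRESHOLD = 3.0


@dataclass
class LengthFit:
    """OLS fit of hap-mer occurrences ~ sequence length."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float
    used_ids: tuple[str, ...] = ()


def fit_length_model(rows: pd.DataFrame, exclude: set[str] | None = None) -> LengthFit:
    """Fit the pooled (both haplotypes) length ~ hap-mer background.

    ``rows`` needs columns seq_id, length_bp, hapmer_occurrences.  When the
    response has zero variance the fit degenerates to a flat line with
    R^2 defined as 0.
    """
    data = rows if not exclude else rows[~rows["seq_id"].isin(exclude)]
    if len(data) < 3:
        raise ValueError(f"need >= 3 sequences to fit background, got {len(data)}")
    x = data["length_bp"].to_numpy(dtype=float)
    y = data["hapmer_occurrences"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: zero length variance")
    if np.ptp(y) == 0:
        return LengthFit(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, n=len(data),
            residual_sd=0.0, used_ids=tuple(data["seq_id"]),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(model.ssr / model.df_resid)) if model.df_resid > 0 else 0.0
    return LengthFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=len(data),
        residual_sd=resid_sd,
        used_ids=tuple(data["seq_id"]),
    )


def _studentized_vs_fit(rows: pd.DataFrame, fit_rows: pd.DataFrame) -> np.ndarray:
    """Externally studentized residual of every row against a background fit.

    Rows inside the fit get the standard leave-one-out studentized
    residual; rows outside it get the prediction-interval t statistic
    (residual over s*sqrt(1 + x0'(X'X)^-1 x0)).
    """
    x_fit = fit_rows["length_bp"].to_numpy(dtype=float)
    y_fit = fit_rows["hapmer_occurrences"].to_numpy(dtype=float)
    X_fit = sm.add_constant(x_fit)
    model = sm.OLS(y_fit, X_fit).fit()
    if model.df_resid < 2 or np.ptp(y_fit) == 0:
        return np.zeros(len(rows))
    infl = OLSInfluence(model)
    t_ext = infl.resid_studentized_external
    s = float(np.sqrt(model.ssr / model.df_resid))
    xtx_inv = np.linalg.inv(X_fit.T @ X_fit)

    fit_index = {sid: i for i, sid in enumerate(fit_rows["seq_id"])}
    out = np.zeros(len(rows))
    for r, (_, row) in enumerate(rows.iterrows()):
        sid = row["seq_id"]
        if sid in fit_index:
            out[r] = t_ext[fit_index[sid]]
        else:
            x0 = np.array([1.0, float(row["length_bp"])])
            pred = float(x0 @ model.params)
            se = s * np.sqrt(1.0 + x0 @ xtx_inv @ x0)
            out[r] = (float(row["hapmer_occurrences"]) - pred) / se if se > 0 else 0.0
    return out


def flag_regression_outliers(
    rows: pd.DataFrame,
    t_threshold: float = T_THRESHOLD,
    refit: bool = True,
) -> tuple[pd.DataFrame, LengthFit]:
    """Flag excess/dearth sequences against the pooled length fit.

    Returns ``rows`` extended with studentized_residual and
    regression_flag columns, plus the (refit) background fit.  With
    ``refit`` a single second pass re-fits the background without the
    first-pass flags and re-evaluates every sequence against it.
    """
    rows = rows.reset_index(drop=True)
    fit = fit_length_model(rows)
    if fit.residual_sd == 0.0 and fit.r_squared == 0.0 and fit.slope == 0.0:
        # zero response variance: nothing to studentize against
        out = rows.copy()
        out["studentized_residual"] = 0.0
        out["regression_flag"] = "none"
        return out, fit

    t = _studentized_vs_fit(rows, rows)
    flagged = set(rows.loc[np.abs(t) > t_threshold, "seq_id"])
    if refit and flagged and len(rows) - len(flagged) >= 3:
        fit_rows = rows[~rows["seq_id"].isin(flagged)]
        if np.ptp(fit_rows["length_bp"].to_numpy(dtype=float)) > 0:
            t = _studentized_vs_fit(rows, fit_rows)
            fit = fit_length_model(rows, exclude=flagged)

    out = rows.copy()
    out["studentized_residual"] = t
    out["regression_flag"] = np.select(
        [t > t_threshold, t < -t_threshold], ["excess", "dearth"], default="none"
    )
    return out, fit


@dataclass
class BoxplotSummary:
    haplotype: str
    q1: float
    median: float
    q3: float
    lower_fence: float
    upper_fence: float
    minimum: float
    maximum: float


def tukey_fences(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """(q1, median, q3, lower fence, upper fence); linear-interpolated quartiles."""
    q1, med, q3 = (float(v) for v in np.percentile(values, [25, 50, 75]))
    iqr = q3 - q1
    return q1, med, q3, q1 - 1.5 * iqr, q3 + 1.5 * iqr


def boxplot_flags(rows: pd.DataFrame) -> tuple[pd.DataFrame, list[BoxplotSummary]]:
    """Tukey-fence flags on density_per_mb, per haplotype.

    Haplotypes with fewer than 4 sequences get no flags (fences on so few
    points are meaningless) but still appear in the summary.
    """
    out = rows.copy()
    out["boxplot_flag"] = "none"
    summaries = []
    for hap, grp in rows.groupby("haplotype", sort=False):
        dens = grp["density_per_mb"].to_numpy(dtype=float)
        q1, med, q3, lo, hi = tukey_fences(dens)
        summaries.append(
            BoxplotSummary(
                haplotype=hap, q1=q1, median=med, q3=q3,
                lower_fence=lo, upper_fence=hi,
                minimum=float(dens.min()), maximum=float(dens.max()),
            )
        )
        if len(grp) < 4:
            logger.warning("%s: <4 sequences, skipping boxplot flags", hap)
            continue
        flag = np.select([dens > hi, dens < lo], ["high", "low"], default="none")
        out.loc[grp.index, "boxplot_flag"] = flag
    return out, summaries


def summarize_pairs(
    pairs: list,
    seq_table: pd.DataFrame,
    window_tracks: dict,
    identity_medians: dict[tuple[str, str], float],
    m_consecutive: int = 3,
    dearth_identity_ratio: float = 0.5,
) -> pd.DataFrame:
    """Converge per-sequence flags, window densities, and identity into pair calls.

    ``window_tracks`` maps (haplotype, seq_id) -> WindowTrack;
    ``identity_medians`` maps (hap1_id, hap2_id) -> median window
    shared_fraction for that pair.  The autosomal per-window background is
    built from all windows of unflagged pairs.

    A dearth call requires a low-flagged member AND identity near 1 in the
    scale-free sense: the pair's non-shared k-mer fraction (1 - median
    shared fraction, a monotone proxy of its heterozygosity) must be below
    ``dearth_identity_ratio`` times the autosomal background's — background
    pairs sit at ratio ~1 whatever the heterozygosity, a genuinely
    diversity-depleted pair far below it.
    """
    flags = seq_table.set_index(["haplotype", "seq_id"])

    def member_flags(p) -> tuple[str, str, str, str]:
        r1 = flags.loc[("hap1", p.hap1_id)]
        r2 = flags.loc[("hap2", p.hap2_id)]
        return (
            str(r1["regression_flag"]), str(r1["boxplot_flag"]),
            str(r2["regression_flag"]), str(r2["boxplot_flag"]),
        )

    unflagged = [
        p for p in pairs
        if member_flags(p) == ("none", "none", "none", "none")
    ]
    if not unflagged:
        raise RuntimeError("no autosomal background: every pair has a flagged member")

    bg_window_dens = np.concatenate(
        [
            window_tracks[(hap, sid)].density_per_mb
            for p in unflagged
            for hap, sid in (("hap1", p.hap1_id), ("hap2", p.hap2_id))
        ]
    )
    _, _, _, _, window_fence = tukey_fences(bg_window_dens)

    bg_medians = np.array(
        [identity_medians[(p.hap1_id, p.hap2_id)] for p in unflagged], dtype=float
    )
    bg_medians = bg_medians[~np.isnan(bg_medians)]
    bg_nonshared = float(1.0 - np.median(bg_medians)) if bg_medians.size else 0.0

    records = []
    for p in pairs:
        rf1, bf1, rf2, bf2 = member_flags(p)
        excess_member = "excess" in (rf1, rf2) or "high" in (bf1, bf2)
        dearth_member = "dearth" in (rf1, rf2) or "low" in (bf1, bf2)
        run = max(
            max_consecutive_true(window_tracks[("hap1", p.hap1_id)].density_per_mb > window_fence),
            max_consecutive_true(window_tracks[("hap2", p.hap2_id)].density_per_mb > window_fence),
        )
        med_ident = identity_medians.get((p.hap1_id, p.hap2_id), float("nan"))
        call = "none"
        if excess_member and run >= m_consecutive:
            call = "excess"
        elif (
            dearth_member
            and not np.isnan(med_ident)
            and (1.0 - med_ident) < dearth_identity_ratio * bg_nonshared
        ):
            call = "dearth"
        records.append(
            {
                "hap1_id": p.hap1_id,
                "hap2_id": p.hap2_id,
                "pair_flag": call,
                "n_flagged_members": int(excess_member) + int(dearth_member),
                "max_consecutive_high_windows": run,
                "window_upper_fence": window_fence,
                "median_shared_fraction": med_ident,
            }
        )
    return pd.DataFrame(records)
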