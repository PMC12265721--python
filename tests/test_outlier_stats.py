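import numpy as np
import pandas as pd
import pytest

from hapmerscan.outlier_stats import (
    boxplot_flags,
    fit_length_model,
    flag_regression_outliers,
    tukey_fences,
)
from oracles import ols_closed_form, studentized_loo


def _rows(lengths, counts, haplotype="hap1"):
    return pd.DataFrame(
        {
            "haplotype": haplotype,
            "seq_id": [f"s{i}" for i in range(len(lengths))],
            "length_bp": lengths,
            "hapmer_occurrences": counts,
        }
    )


class TestFitLengthModel:
    def test_exact_line(self):
        fit = fit_length_model(_rows([1e6, 2e6, 3e6], [100, 200, 300]))
        assert fit.slope == pytest.approx(1e-4)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_outlier_reduces_r2_and_dominates_residuals(self):
        rows = _rows([1e6, 2e6, 3e6, 1.5e6], [100, 200, 300, 5000])
        fit = fit_length_model(rows)
        assert fit.r_squared < 1.0
        out, _ = flag_regression_outliers(rows, refit=False)
        t = out["studentized_residual"].abs()
        assert t.idxmax() == 3

    def test_degenerate_zero_count_variance(self):
        fit = fit_length_model(_rows([1e6, 2e6, 3e6], [7, 7, 7]))
        assert fit.slope == 0.0 and fit.r_squared == 0.0

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_length_model(_rows([1e6, 2e6], [1, 2]))

    def test_zero_length_variance(self):
        with pytest.raises(ValueError, match="degenerate design"):
            fit_length_model(_rows([1e6, 1e6, 1e6], [1, 2, 3]))

    def test_matches_closed_form_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.uniform(5e5, 5e6, n)
            y = 1e-4 * x + rng.normal(0, 50, n)
            fit = fit_length_model(_rows(x, y))
            slope, intercept, r2, sd = ols_closed_form(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-9)
            assert fit.intercept == pytest.approx(intercept, rel=1e-9)
            assert fit.r_squared == pytest.approx(r2, rel=1e-9)
            assert fit.residual_sd == pytest.approx(sd, rel=1e-9)


class TestStudentizedResiduals:
    def test_matches_brute_force_loo(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 20))
            x = rng.uniform(5e5, 5e6, n)
            y = 2e-4 * x + rng.normal(0, 100, n)
            out, _ = flag_regression_outliers(_rows(x, y), refit=False)
            expect = studentized_loo(x, y)
            np.testing.assert_allclose(
                out["studentized_residual"].to_numpy(), expect, rtol=1e-8
            )

    def test_perfect_line_no_flags(self):
        out, _ = flag_regression_outliers(_rows([1e6, 2e6, 3e6, 4e6], [100, 200, 300, 400]))
        assert (out["regression_flag"] == "none").all()

    def test_excess_and_dearth_direction(self):
        base_x = list(np.linspace(1e6, 5e6, 9))
        base_y = [x * 1e-4 for x in base_x]
        hi = _rows(base_x + [3.2e6], base_y + [5000])
        out, _ = flag_regression_outliers(hi)
        assert out.loc[9, "regression_flag"] == "excess"
        lo = _rows(base_x + [3.2e6], base_y + [0.0])
        out, _ = flag_regression_outliers(lo)
        assert out.loc[9, "regression_flag"] == "dearth"

    def test_scaling_a_count_up_never_moves_toward_dearth(self, rng):
        x = rng.uniform(1e6, 5e6, 12)
        y = 1e-4 * x + rng.normal(0, 30, 12)
        rows = _rows(x, y)
        out1, _ = flag_regression_outliers(rows, refit=False)
        rows2 = rows.copy()
        rows2.loc[4, "hapmer_occurrences"] *= 10
        out2, _ = flag_regression_outliers(rows2, refit=False)
        order = {"dearth": 0, "none": 1, "excess": 2}
        assert order[out2.loc[4, "regression_flag"]] >= order[out1.loc[4, "regression_flag"]]

    def test_refit_keeps_background_flags_stable(self):
        """With one true outlier, the refit pass always flags it, and at
        least 95% of background sequences keep the flag they had before
        the refit (only points sitting right at the 3-sigma boundary may
        toggle, which Gaussian tails make unavoidable for a few)."""
        stable = total = 0
        trials = 40
        n = 20
        for i in range(trials):
            r = np.random.default_rng(1000 + i)
            x = r.uniform(5e5, 3e6, n)
            y = 1e-4 * x + r.normal(0, 15.0, n)
            rows = _rows(np.append(x, 2e6), np.append(y, 1e5))
            out_single, _ = flag_regression_outliers(rows, refit=False)
            out_refit, _ = flag_regression_outliers(rows, refit=True)
            assert out_refit.loc[n, "regression_flag"] == "excess"
            same = (
                out_refit.loc[: n - 1, "regression_flag"]
                == out_single.loc[: n - 1, "regression_flag"]
            )
            stable += int(same.sum())
            total += n
        assert stable >= 0.95 * total


class TestBoxplotFlags:
    def test_hand_computed_fences(self):
        dens = [1.0, 2.0, 3.0, 4.0, 100.0]
        q1, med, q3, lo, hi = tukey_fences(np.array(dens))
        assert (q1, q3) == (2.0, 4.0)
        assert hi == 7.0
        rows = pd.DataFrame(
            {
                "haplotype": "hap1",
                "seq_id": [f"s{i}" for i in range(5)],
                "density_per_mb": dens,
            }
        )
        out, summaries = boxplot_flags(rows)
        assert out["boxplot_flag"].tolist() == ["none"] * 4 + ["high"]
        assert summaries[0].upper_fence == 7.0

    def test_all_equal_densities_no_flags(self):
        rows = pd.DataFrame(
            {"haplotype": "hap1", "seq_id": list("abcd"), "density_per_mb": [5.0] * 4}
        )
        out, _ = boxplot_flags(rows)
        assert (out["boxplot_flag"] == "none").all()

    def test_fewer_than_four_sequences_no_flags_summary_emitted(self):
        rows = pd.DataFrame(
            {"haplotype": "hap1", "seq_id": list("abc"), "density_per_mb": [1.0, 2.0, 90.0]}
        )
        out, summaries = boxplot_flags(rows)
        assert (out["boxplot_flag"] == "none").all()
        assert len(summaries) == 1
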