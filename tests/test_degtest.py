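"""DEG testing: exact conditional test oracle, adjustment, calling, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from gxetx import degtest
from gxetx.degtest import DegSet, adjust_pvalues, call_degs, summarize_contrast
from gxetx.expression import CountMatrix, validate_design
from gxetx.simulate import SimConfig, simulate_counts


def two_group_design(reps=3):
    rows = []
    for group, geno, site in [
        ("DA", "transgenic", "saline"), ("DB", "progenitor", "saline"),
        ("QA", "transgenic", "nonsaline"), ("QB", "progenitor", "nonsaline"),
    ]:
        for r in range(1, reps + 1):
            rows.append({"sample_id": f"{group}_{r}", "genotype": geno,
                         "site": site, "replicate": r})
    return validate_design(pd.DataFrame(rows))


def matrix_for(groups_counts, reps=3, lib=1_000_000, length=1000.0):
    """CountMatrix with per-group replicate count vectors and fixed library sizes."""
    design = two_group_design(reps)
    data = {}
    for g in ["DA", "DB", "QA", "QB"]:
        for r in range(reps):
            data[f"{g}_{r + 1}"] = [row[g][r] for row in groups_counts]
    idx = [f"g{i}" for i in range(len(groups_counts))]
    cm = CountMatrix(
        pd.DataFrame(data, index=idx),
        pd.Series(length, index=idx),
        library_sizes=pd.Series(float(lib), index=list(design["sample_id"])),
    )
    return cm, design


def exact_conditional_p(xa: int, xb: int, p0: float) -> float:
    """Independent enumeration oracle: two-sided exact conditional binomial
    p-value, summing P(X=j) over outcomes no more likely than observed."""
    t = xa + xb
    probs = [math.comb(t, j) * p0**j * (1 - p0) ** (t - j) for j in range(t + 1)]
    obs = probs[xa]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-12)))


class TestExactConditionalTest:
    def test_all_or_nothing_closed_form(self):
        # counts A=(30,30,30), B=(0,0,0), equal libraries -> p = 2 * 0.5^90
        cm, design = matrix_for([
            {"DA": [30, 30, 30], "DB": [0, 0, 0], "QA": [5, 5, 5], "QB": [5, 5, 5]},
            {"DA": [900, 900, 900], "DB": [900, 900, 900],
             "QA": [900, 900, 900], "QB": [900, 900, 900]},
        ])
        res = degtest.test_contrast(cm, design, "DA", "DB")
        assert res.table.loc["g0", "pvalue"] == pytest.approx(2 * 0.5**90, rel=1e-9)

    def test_symmetric_null_gives_p_one_and_zero_lfc(self):
        cm, design = matrix_for([
            {"DA": [50, 50, 50], "DB": [50, 50, 50],
             "QA": [50, 50, 50], "QB": [50, 50, 50]},
        ])
        res = degtest.test_contrast(cm, design, "DA", "DB")
        assert res.table.loc["g0", "pvalue"] == pytest.approx(1.0)
        assert res.table.loc["g0", "log2fc"] == pytest.approx(0.0)

    def test_group_swap_negates_lfc_and_keeps_p(self):
        cm, design = matrix_for([
            {"DA": [80, 95, 70], "DB": [20, 25, 30],
             "QA": [50, 50, 50], "QB": [50, 50, 50]},
        ])
        fwd = degtest.test_contrast(cm, design, "DA", "DB")
        rev = degtest.test_contrast(cm, design, "DB", "DA")
        assert fwd.table.loc["g0", "log2fc"] == pytest.approx(-rev.table.loc["g0", "log2fc"])
        assert fwd.table.loc["g0", "pvalue"] == pytest.approx(rev.table.loc["g0", "pvalue"])

    def test_matches_enumeration_oracle_on_small_counts(self):
        """Exact-test p-values agree with exhaustive enumeration of the
        conditional binomial distribution (pooled totals <= 50)."""
        rng = np.random.default_rng(42)
        rows = []
        for _ in range(25):
            rows.append({
                "DA": list(rng.integers(0, 9, 3)), "DB": list(rng.integers(0, 9, 3)),
                "QA": [5, 5, 5], "QB": [5, 5, 5],
            })
        # large lengths keep FPKM above filter despite tiny counts
        cm, design = matrix_for(rows, lib=10_000, length=1000.0)
        res = degtest.test_contrast(cm, design, "DA", "DB")
        for i, row in enumerate(rows):
            xa, xb = sum(row["DA"]), sum(row["DB"])
            expected = exact_conditional_p(xa, xb, 0.5)
            got = res.table.loc[f"g{i}", "pvalue"]
            if np.isnan(got):  # filtered out by expression threshold
                continue
            assert got == pytest.approx(expected, rel=1e-9), (xa, xb)

    def test_unequal_library_sizes_shift_the_null(self):
        cm, design = matrix_for([
            {"DA": [100, 100, 100], "DB": [50, 50, 50],
             "QA": [5, 5, 5], "QB": [5, 5, 5]},
        ])
        # library of A twice that of B: pooled 300 vs 150 is exactly the null
        cm.library_sizes[["DA_1", "DA_2", "DA_3"]] = 2_000_000.0
        res = degtest.test_contrast(cm, design, "DA", "DB")
        assert res.table.loc["g0", "pvalue"] == pytest.approx(1.0)

    def test_nb_variant_runs_and_is_calibrated_direction(self):
        cm, design = matrix_for([
            {"DA": [200, 220, 210], "DB": [50, 55, 60],
             "QA": [50, 50, 50], "QB": [50, 50, 50]},
            {"DA": [100, 101, 99], "DB": [100, 102, 98],
             "QA": [50, 50, 50], "QB": [50, 50, 50]},
        ])
        res = degtest.test_contrast(cm, design, "DA", "DB", test="nb-moments")
        assert res.table.loc["g0", "pvalue"] < 0.01
        assert res.table.loc["g1", "pvalue"] > 0.2

    def test_zero_total_group_rejected(self):
        cm, design = matrix_for([
            {"DA": [0, 0, 0], "DB": [0, 0, 0], "QA": [1, 1, 1], "QB": [1, 1, 1]},
        ])
        with pytest.raises(ValueError, match="zero total"):
            degtest.test_contrast(cm, design, "DA", "DB")


class TestAdjustment:
    def test_bh_step_up_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03], "bh"), [0.03, 0.03, 0.03]
        )

    def test_bonferroni_multiplication(self):
        out = adjust_pvalues([0.01, 0.5, 0.7, 0.9, 1.0], "bonferroni")
        assert out[0] == pytest.approx(0.05)
        assert out[-1] == 1.0  # clipped

    def test_single_p_unchanged(self):
        for method in ("bh", "bonferroni"):
            assert adjust_pvalues([0.037], method)[0] == pytest.approx(0.037)

    def test_adjusted_at_least_raw_and_order_preserved(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        adj = adjust_pvalues(p, "bh")
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.1, 1.5])
        with pytest.raises(ValueError):
            adjust_pvalues([-0.1])


class TestCallDegs:
    def make_result(self, log2fc, padj, expressed=True):
        from gxetx.degtest import ContrastResult
        table = pd.DataFrame({
            "mean_fpkm_a": 10.0, "mean_fpkm_b": 10.0,
            "log2fc": [log2fc], "pvalue": [padj], "padj": [padj],
            "expressed": [expressed], "coexpressed": [expressed],
        }, index=["g0"])
        return ContrastResult("DA-vs-DB", "DA", "DB", table)

    def test_boundaries_inclusive(self):
        degs = call_degs(self.make_result(1.0, 0.05))
        assert degs.directions == {"g0": 1}
        degs = call_degs(self.make_result(-1.0, 0.05))
        assert degs.directions == {"g0": -1}

    def test_just_below_lfc_threshold_not_a_deg(self):
        assert len(call_degs(self.make_result(0.99, 1e-9))) == 0

    def test_filtered_gene_never_a_deg(self):
        assert len(call_degs(self.make_result(5.0, 1e-9, expressed=False))) == 0

    def test_up_down_disjoint_on_synthetic_fit(self, small_fit):
        for degs in small_fit.deg_sets.values():
            assert not (degs.up & degs.down)

    def test_sensitivity_on_planted_effects(self):
        """Non-null genes at effect 2 log2, dispersion 0.05, 3 replicates
        are detected with sensitivity >= 0.8."""
        cfg = SimConfig(n_genes=600, dispersion=0.05, effect_size_log2=2.0, seed=21)
        cm, design, truth = simulate_counts(cfg)
        res = degtest.test_contrast(cm, design, "DA", "DB")
        degs = call_degs(res)
        # genes with a genuine genotype shift at the saline site
        t = truth.table
        affected = set(t.index[(t["sign_genotype"] != 0)])
        assert affected, "fixture must plant genotype-affected genes"
        hit = sum(1 for g in affected if g in degs.genes)
        assert hit / len(affected) >= 0.8


class TestSummaries:
    @pytest.mark.parametrize(
        "total,coexpressed,expected",
        [(258, 19_719, "1.31%"), (1_049, 19_775, "5.30%"),
         (1_086, 19_618, "5.54%"), (0, 1000, "0.00%")],
    )
    def test_percentage_formatting(self, total, coexpressed, expected):
        degs = DegSet("c", {f"g{i}": 1 for i in range(total)})
        assert summarize_contrast(degs, coexpressed)["pct_formatted"] == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            summarize_contrast(DegSet("c", {}), 0)

    def test_inconsistent_denominator_rejected(self):
        degs = DegSet("c", {"a": 1, "b": -1})
        with pytest.raises(ValueError):
            summarize_contrast(degs, 1)
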