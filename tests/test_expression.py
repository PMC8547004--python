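"""Normalization identities, NB test behavior, BH adjustment, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from panstrata.expression import (
    NormalizationError,
    SampleSheet,
    bh_adjust,
    call_degs,
    compute_rpkm,
    compute_tpm,
    de_test,
    estimate_dispersion_mom,
    nb_wald_test,
    size_factors_median_ratio,
    stratum_expression_summary,
)


def frame(rows, genes=None, samples=None):
    rows = np.atleast_2d(rows)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


class TestTPM:
    def test_single_gene_gets_the_whole_million(self):
        tpm = compute_tpm(frame([[7]]), pd.Series({"g0": 500}))
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_per_kb_rates_split_evenly(self):
        tpm = compute_tpm(
            frame([[5], [10]]), pd.Series({"g0": 500, "g1": 1000})
        )
        assert tpm["s0"].tolist() == pytest.approx([5e5, 5e5])

    def test_three_gene_worked_example(self):
        tpm = compute_tpm(
            frame([[10], [10], [10]]),
            pd.Series({"g0": 1000, "g1": 2000, "g2": 500}),
        )
        assert tpm["s0"].to_numpy() == pytest.approx(
            [285714.2857, 142857.1429, 571428.5714], rel=1e-8
        )

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(0)
        counts = frame(rng.integers(0, 100, size=(50, 4)))
        lengths = pd.Series(rng.integers(200, 3000, size=50),
                            index=counts.index)
        tpm = compute_tpm(counts, lengths)
        assert tpm.sum(axis=0).to_numpy() == pytest.approx([1e6] * 4, rel=1e-9)

    def test_scale_invariance_per_sample(self):
        counts = frame([[3, 6], [9, 18]])
        lengths = pd.Series({"g0": 100, "g1": 700})
        tpm = compute_tpm(counts, lengths)
        assert tpm["s0"].to_numpy() == pytest.approx(tpm["s1"].to_numpy())

    def test_all_zero_sample_warns_and_zeros(self):
        with pytest.warns(UserWarning, match="all-zero"):
            tpm = compute_tpm(frame([[5, 0]]), pd.Series({"g0": 100}))
        assert tpm["s1"].tolist() == [0.0]


class TestRPKM:
    def test_worked_example(self):
        counts = frame([[50], [999950]])
        lengths = pd.Series({"g0": 2000, "g1": 1000})
        # library size 1e6, len 2 kb, 50 reads -> 25
        assert compute_rpkm(counts, lengths).iloc[0, 0] == pytest.approx(25.0)

    def test_whole_library_single_gene(self):
        counts = frame([[1000]])
        assert compute_rpkm(counts, pd.Series({"g0": 1000})).iloc[0, 0] == (
            pytest.approx(1e6)
        )

    def test_depth_invariance(self):
        counts = frame([[3, 6], [9, 18]])
        lengths = pd.Series({"g0": 100, "g1": 700})
        rpkm = compute_rpkm(counts, lengths)
        assert rpkm["s0"].to_numpy() == pytest.approx(rpkm["s1"].to_numpy())


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = frame([[10, 10], [3, 3]])
        assert size_factors_median_ratio(counts).to_numpy() == pytest.approx(
            [1.0, 1.0]
        )

    def test_doubled_sample_splits_geometrically(self):
        counts = frame([[10, 20], [4, 8], [100, 200]])
        sf = size_factors_median_ratio(counts)
        assert sf.to_numpy() == pytest.approx([2 ** -0.5, 2 ** 0.5])

    def test_scaling_one_sample_scales_its_relative_factor(self):
        # the geometric-mean reference absorbs c**(1/n), so the clean
        # invariant is on factor ratios: sf[j]/sf[i] gains exactly c
        rng = np.random.default_rng(1)
        counts = frame(rng.integers(1, 200, size=(60, 3)))
        sf = size_factors_median_ratio(counts)
        scaled = counts.copy()
        scaled["s1"] = counts["s1"] * 3
        sf2 = size_factors_median_ratio(scaled)
        assert sf2["s1"] / sf2["s0"] == pytest.approx(3.0 * sf["s1"] / sf["s0"])
        assert sf2["s2"] / sf2["s0"] == pytest.approx(sf["s2"] / sf["s0"])
        # and the reference pull is exactly c**(1/n) on untouched samples
        assert sf2["s0"] == pytest.approx(sf["s0"] / 3 ** (1 / 3))

    def test_no_all_positive_gene_is_an_error(self):
        counts = frame([[0, 5], [5, 0]])
        with pytest.raises(NormalizationError, match="pseudo-reference"):
            size_factors_median_ratio(counts)


class TestDispersion:
    GROUPS = {"ref": ["s0", "s1", "s2", "s3", "s4"],
              "trt": ["s5", "s6", "s7", "s8", "s9"]}

    def test_constant_gene_hits_the_floor(self):
        counts = frame([[50] * 10])
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion_mom(counts, sf, self.GROUPS)
        assert alpha.iloc[0] == pytest.approx(1e-8)

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(3)
        counts = frame(rng.poisson(200, size=(5000, 10)))
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion_mom(counts, sf, self.GROUPS)
        assert alpha.median() <= 1e-2

    def test_nb_alpha_recovered_within_band(self):
        rng = np.random.default_rng(4)
        a, mu = 0.5, 200.0
        groups = {"ref": [f"s{i}" for i in range(20)],
                  "trt": [f"s{i}" for i in range(20, 40)]}
        counts = frame(
            rng.negative_binomial(1 / a, 1 / (1 + a * mu), size=(3000, 40)),
            samples=groups["ref"] + groups["trt"],
        )
        sf = pd.Series(1.0, index=counts.columns)
        alpha = estimate_dispersion_mom(counts, sf, groups)
        assert 0.35 <= alpha.median() <= 0.65


class TestWaldTest:
    GROUPS = {"ref": ["r1", "r2", "r3"], "trt": ["t1", "t2", "t3"]}

    def _run(self, ref_counts, trt_counts, alpha=0.1):
        counts = frame(
            [list(r) + list(t) for r, t in zip(ref_counts, trt_counts)],
            samples=self.GROUPS["ref"] + self.GROUPS["trt"],
        )
        sf = pd.Series(1.0, index=counts.columns)
        disp = pd.Series(alpha, index=counts.index)
        return nb_wald_test(counts, sf, disp, self.GROUPS, "ref", "trt")

    def test_identical_groups_are_null(self):
        res = self._run([[10, 10, 10]], [[10, 10, 10]])
        assert res["log2fc"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_exact_fourfold_change(self):
        res = self._run([[10, 10, 10]], [[40, 40, 40]])
        assert res["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_both_groups_zero_gets_p_one(self):
        res = self._run([[0, 0, 0]], [[0, 0, 0]])
        assert res["p"].iloc[0] == 1.0
        assert res["log2fc"].iloc[0] == 0.0

    def test_one_zero_group_uses_pseudocount(self):
        res = self._run([[0, 0, 0]], [[8, 8, 8]])
        assert res["log2fc"].iloc[0] == pytest.approx(np.log2(8.5 / 0.5))
        assert res["p"].iloc[0] < 1.0

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(17)
        n, a = 10, 0.1
        groups = {"ref": [f"r{i}" for i in range(n)],
                  "trt": [f"t{i}" for i in range(n)]}
        mu = np.exp(rng.uniform(np.log(20), np.log(2000), 10_000))
        counts = frame(
            rng.negative_binomial(
                1 / a, 1 / (1 + a * np.tile(mu[:, None], (1, 2 * n)))
            ),
            samples=groups["ref"] + groups["trt"],
        )
        res = de_test(counts, groups["ref"], groups["trt"])
        assert 0.025 <= (res["p"] < 0.05).mean() <= 0.075
        assert res["deg"].mean() < 0.005


class TestBH:
    def test_step_up_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_all_equal_ps_unchanged(self):
        assert bh_adjust([0.07] * 5).tolist() == pytest.approx([0.07] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_statsmodels_and_dominates_raw(self, ps):
        q = bh_adjust(ps)
        q_ref = multipletests(ps, method="fdr_bh")[1]
        assert q == pytest.approx(q_ref, abs=1e-12)
        assert (q >= np.asarray(ps) - 1e-15).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestDEGRule:
    @pytest.mark.parametrize(
        "log2fc,q,expect_deg,expect_dir",
        [
            (1.0, 0.001, False, "ns"),   # threshold is strict
            (2.0, 0.01, True, "up"),
            (-1.5, 0.04, True, "down"),
            (3.0, 0.2, False, "ns"),
            (0.5, 0.001, False, "ns"),
        ],
    )
    def test_strict_thresholds(self, log2fc, q, expect_deg, expect_dir):
        de = pd.DataFrame({"log2fc": [log2fc], "p": [q], "q": [q]})
        out = call_degs(de)
        assert bool(out["deg"].iloc[0]) is expect_deg
        assert out["direction"].iloc[0] == expect_dir


def _sheet(n=2, treatments=("wt", "mut")):
    rows = []
    for t in treatments:
        for i in range(n):
            rows.append((f"{t}_{i}", "host", t, i + 1))
    df = pd.DataFrame(
        rows, columns=["sample", "organism", "treatment", "replicate"]
    ).set_index("sample")
    return SampleSheet(df, reference=treatments[0])


class TestStratumSummary:
    def test_constant_genes_have_degenerate_ci(self):
        sheet = _sheet()
        tpm = frame([[100.0] * 4, [100.0] * 4],
                    samples=list(sheet.frame.index))
        strata = pd.DataFrame(
            {"stratum": ["s1", "s1"], "copy_class": ["single", "single"]},
            index=tpm.index,
        )
        out = stratum_expression_summary(tpm, strata, sheet, n_boot=100, seed=0)
        row = out[(out.stratum == "s1") & (out.copy_class == "single")].iloc[0]
        assert (row.mean_tpm, row.ci_lower, row.ci_upper) == (100.0, 100.0, 100.0)

    def test_single_gene_stratum_ci_is_point(self):
        sheet = _sheet()
        tpm = frame([[10.0, 20.0, 30.0, 40.0]], samples=list(sheet.frame.index))
        strata = pd.DataFrame({"stratum": ["s1"], "copy_class": ["multi"]},
                              index=tpm.index)
        out = stratum_expression_summary(tpm, strata, sheet, n_boot=50, seed=1)
        row = out[(out.copy_class == "multi") & (out.treatment == "wt")].iloc[0]
        assert row.ci_lower == row.ci_upper == row.mean_tpm == 15.0

    def test_empty_stratum_reported_not_raised(self):
        sheet = _sheet()
        tpm = frame([[1.0] * 4], samples=list(sheet.frame.index))
        strata = pd.DataFrame({"stratum": ["s1"], "copy_class": ["single"]},
                              index=tpm.index)
        out = stratum_expression_summary(tpm, strata, sheet, n_boot=10, seed=0)
        empty = out[(out.stratum == "s1") & (out.copy_class == "multi")]
        assert (empty["n_genes"] == 0).all()
        assert empty["mean_tpm"].isna().all()

    def test_bootstrap_ci_coverage_near_nominal(self):
        # genes i.i.d. around a known mean; the 95% CI should cover it ~95%
        sheet = _sheet()
        cover = 0
        reps = 200
        for r in range(reps):
            rng = np.random.default_rng(r)
            vals = rng.normal(50, 10, size=(300, 4))
            tpm = frame(vals, samples=list(sheet.frame.index))
            strata = pd.DataFrame(
                {"stratum": "s1", "copy_class": "single"}, index=tpm.index
            )
            out = stratum_expression_summary(tpm, strata, sheet,
                                             n_boot=200, seed=r)
            row = out[(out.copy_class == "single") & (out.treatment == "wt")].iloc[0]
            cover += row.ci_lower <= 50.0 <= row.ci_upper
        assert 0.88 <= cover / reps <= 0.99


class TestSampleSheet:
    def test_reference_must_exist(self):
        df = pd.DataFrame(
            {"organism": ["h"] * 2, "treatment": ["a"] * 2, "replicate": [1, 2]},
            index=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="reference"):
            SampleSheet(df, reference="zzz")

    def test_single_replicate_treatment_rejected(self):
        df = pd.DataFrame(
            {"organism": ["h"] * 3, "treatment": ["a", "a", "b"],
             "replicate": [1, 2, 1]},
            index=["s1", "s2", "s3"],
        )
        with pytest.raises(ValueError, match="replicates"):
            SampleSheet(df, reference="a")
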