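"""Volcano statistics: transform, imputation, t-tests, s0 classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import betainc

from decaplex import (
    DEFAULT_CUTOFFS,
    SIG_A,
    SIG_B,
    CutoffSpec,
    LfqMatrix,
    classify_significance,
    default_design,
    enrichment_ratio,
    filter_min_values,
    impute_downshifted,
    log_transform,
    pearson_between,
    pooled_ttest,
    simulate_lfq,
    two_sample_ttest,
)


def analytic_two_tailed_p(a, b):
    """Independent oracle: pooled t-test p via the regularized incomplete beta.

    For t with nu degrees of freedom the two-tailed p-value is
    I_{nu/(nu+t^2)}(nu/2, 1/2).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    nu = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / nu
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return betainc(nu / 2.0, 0.5, nu / (nu + t * t))


# ---------------------------------------------------------------------------
# log transform
# ---------------------------------------------------------------------------

class TestLogTransform:
    def test_value_and_missing(self):
        values = pd.DataFrame({"s1": [1024.0, np.nan], "s2": [2.0, 8.0]},
                              index=["P1", "P2"])
        out = log_transform(LfqMatrix(values))
        assert out.values.loc["P1", "s1"] == 10.0
        assert np.isnan(out.values.loc["P2", "s1"])
        assert out.log_transformed

    def test_double_transform_rejected(self):
        matrix = LfqMatrix(pd.DataFrame({"s1": [4.0, 8.0]}, index=["P1", "P2"]))
        with pytest.raises(ValueError, match="already"):
            log_transform(log_transform(matrix))

    def test_exp2_inverts_transform(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.uniform(1, 1e6, (20, 4)),
                           index=[f"P{i}" for i in range(20)],
                           columns=list("abcd"))
        out = log_transform(LfqMatrix(raw))
        np.testing.assert_allclose(np.exp2(out.values), raw, rtol=1e-12)


# ---------------------------------------------------------------------------
# minimum-values filter
# ---------------------------------------------------------------------------

class TestFilterMinValues:
    def test_counts_match_brute_force(self, toy_matrix):
        for min_count in range(0, 7):
            filtered, traces = filter_min_values(toy_matrix, min_count)
            expected = {
                pid
                for pid in toy_matrix.protein_ids
                if toy_matrix.values.loc[pid].notna().sum() >= min_count
            }
            assert set(filtered.protein_ids) == expected
            # every protein's trace records the rule with the right outcome
            assert {t.protein_id for t in traces if t.passed} == expected

    def test_group_scope(self, toy_matrix):
        bait = ["bait1_1", "bait1_2", "bait1_3"]
        filtered, _ = filter_min_values(toy_matrix, 2, samples=bait)
        expected = {
            pid
            for pid in toy_matrix.protein_ids
            if toy_matrix.values.loc[pid, bait].notna().sum() >= 2
        }
        assert set(filtered.protein_ids) == expected

    def test_min_count_zero_is_identity(self, toy_matrix):
        filtered, _ = filter_min_values(toy_matrix, 0)
        assert filtered.protein_ids == toy_matrix.protein_ids

    def test_excessive_min_count_rejected(self, toy_matrix):
        with pytest.raises(ValueError, match="exceeds"):
            filter_min_values(toy_matrix, 7)

    def test_sparse_protein_removed_at_three_of_all(self):
        # observed in only 2 samples while requiring >= 3 over the whole design
        values = pd.DataFrame(
            np.full((1, 18), np.nan), index=["P0"],
            columns=[f"s{i}" for i in range(18)],
        )
        values.iloc[0, :2] = 20.0
        filtered, _ = filter_min_values(LfqMatrix(values, log_transformed=True), 3)
        assert filtered.n_proteins == 0


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class TestImputation:
    def _matrix_with_missing(self, n_missing=1000, n_obs=2000, seed=0):
        rng = np.random.default_rng(seed)
        col = np.concatenate([rng.normal(25, 2, n_obs), np.full(n_missing, np.nan)])
        values = pd.DataFrame({"s1": col, "s2": rng.normal(25, 2, col.size)},
                              index=[f"P{i}" for i in range(col.size)])
        return LfqMatrix(values, log_transformed=True)

    def test_no_missing_returns_unchanged(self):
        values = pd.DataFrame({"s1": [1.0, 2.0], "s2": [3.0, 4.0]}, index=["a", "b"])
        matrix = LfqMatrix(values, log_transformed=True)
        out = impute_downshifted(matrix, seed=0)
        pd.testing.assert_frame_equal(out.values, values)

    def test_observed_cells_never_modified(self):
        matrix = self._matrix_with_missing()
        out = impute_downshifted(matrix, seed=1)
        mask = matrix.missing_mask
        pd.testing.assert_frame_equal(out.values[~mask].dropna(how="all"),
                                      matrix.values[~mask].dropna(how="all"))
        assert not out.values.isna().any().any()

    def test_imputed_mean_matches_downshifted_normal(self):
        # Monte-Carlo: 1000 imputed cells should average mu - 1.8 sigma
        matrix = self._matrix_with_missing()
        observed = matrix.values["s1"].dropna()
        mu, sigma = observed.mean(), observed.std(ddof=1)
        out = impute_downshifted(matrix, width=0.3, downshift=1.8, seed=2)
        imputed = out.values["s1"][matrix.missing_mask["s1"]]
        sem = 0.3 * sigma / np.sqrt(len(imputed))
        assert abs(imputed.mean() - (mu - 1.8 * sigma)) < 3 * sem

    def test_same_seed_identical(self):
        matrix = self._matrix_with_missing()
        out1 = impute_downshifted(matrix, seed=7)
        out2 = impute_downshifted(matrix, seed=7)
        pd.testing.assert_frame_equal(out1.values, out2.values)

    def test_column_without_distribution_rejected(self):
        values = pd.DataFrame({"s1": [1.0, np.nan, np.nan], "s2": [1.0, 2.0, 3.0]},
                              index=list("abc"))
        with pytest.raises(ValueError, match="s1"):
            impute_downshifted(LfqMatrix(values, log_transformed=True), seed=0)

    def test_requires_log_transformed(self):
        matrix = LfqMatrix(pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"]))
        with pytest.raises(ValueError, match="log2-transformed"):
            impute_downshifted(matrix, seed=0)


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

class TestTTest:
    def test_identical_groups(self):
        diff, se, t, p = pooled_ttest([5, 6, 7], [5, 6, 7])
        assert diff == 0.0
        assert p == 1.0

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pooled_ttest([0.0, 0.0], [1.0, 1.0])

    def test_constant_equal_groups_define_p_one(self):
        diff, se, t, p = pooled_ttest([2.0, 2.0], [2.0, 2.0])
        assert (diff, p) == (0.0, 1.0)

    def test_matches_analytic_oracle(self):
        p_impl = pooled_ttest([8, 9, 10], [5, 6, 7])[3]
        assert p_impl == pytest.approx(analytic_two_tailed_p([8, 9, 10], [5, 6, 7]),
                                       abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(2, 8))
        b = rng.normal(rng.normal(), 1, rng.integers(2, 8))
        assert pooled_ttest(a, b)[3] == pytest.approx(
            analytic_two_tailed_p(a, b), abs=1e-12
        )

    def test_group_swap_negates_diff_preserves_p(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(20, 2, (50, 6)),
                              index=[f"P{i}" for i in range(50)],
                              columns=list("abcdef"))
        matrix = LfqMatrix(values, log_transformed=True)
        fwd = two_sample_ttest(matrix, list("abc"), list("def"))
        rev = two_sample_ttest(matrix, list("def"), list("abc"))
        np.testing.assert_allclose(fwd.data["diff"], -rev.data["diff"], rtol=1e-12)
        np.testing.assert_allclose(fwd.data["p"], rev.data["p"], rtol=1e-12)

    def test_tabular_matches_scalar(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(20, 2, (10, 6)),
                              index=[f"P{i}" for i in range(10)],
                              columns=list("abcdef"))
        table = two_sample_ttest(LfqMatrix(values, log_transformed=True),
                                 list("abc"), list("def"))
        for pid in values.index:
            d, se, t, p = pooled_ttest(values.loc[pid, list("abc")],
                                       values.loc[pid, list("def")])
            assert table.data.loc[pid, "p"] == pytest.approx(p, rel=1e-12)
            assert table.data.loc[pid, "diff"] == pytest.approx(d, rel=1e-12)


# ---------------------------------------------------------------------------
# enrichment ratio
# ---------------------------------------------------------------------------

class TestEnrichmentRatio:
    def test_equal_means_give_one_and_doubling_gives_two(self):
        values = pd.DataFrame(
            {"a1": [5.0, 6.0], "a2": [5.0, 6.0], "b1": [5.0, 5.0], "b2": [5.0, 5.0]},
            index=["Peq", "Pup"],
        )
        ratio = enrichment_ratio(LfqMatrix(values, log_transformed=True),
                                 ["a1", "a2"], ["b1", "b2"])
        assert ratio["Peq"] == pytest.approx(1.0)
        assert ratio["Pup"] == pytest.approx(2.0)

    def test_matches_geometric_mean_quotient(self):
        rng = np.random.default_rng(5)
        raw = np.exp2(rng.normal(20, 2, (20, 4)))
        values = pd.DataFrame(np.log2(raw), index=[f"P{i}" for i in range(20)],
                              columns=["a1", "a2", "b1", "b2"])
        ratio = enrichment_ratio(LfqMatrix(values, log_transformed=True),
                                 ["a1", "a2"], ["b1", "b2"])
        geo = (raw[:, 0] * raw[:, 1]) ** 0.5 / (raw[:, 2] * raw[:, 3]) ** 0.5
        np.testing.assert_allclose(ratio.to_numpy(), geo, rtol=1e-10)


# ---------------------------------------------------------------------------
# s0 classification
# ---------------------------------------------------------------------------

def _classified_table(seed=0, **sim_kwargs):
    design = default_design()
    matrix, truth = simulate_lfq(design=design, seed=seed, **sim_kwargs)
    imputed = log_transform(matrix)
    table = two_sample_ttest(imputed, design.by_group("bait", "bait1"),
                             design.by_group("wt_control"))
    return classify_significance(table, imputed, DEFAULT_CUTOFFS, 100,
                                 seed=seed + 1), truth


class TestClassification:
    def test_zero_diff_never_significant(self):
        table, _ = _classified_table(seed=10, n_proteins=300, n_interactors=10)
        near_zero = table.data["diff"].abs() < 1e-9
        for name in ("SigA", "SigB", "SigC"):
            assert not table.data.loc[near_zero, name].any()

    def test_sig_a_nested_in_sig_b(self):
        table, _ = _classified_table(seed=11, n_proteins=500, n_interactors=25)
        assert table.significant("SigA") <= table.significant("SigB")
        assert table.thresholds["SigA"] >= table.thresholds["SigB"]

    def test_class_region_monotone_in_diff(self):
        # at a fixed threshold, growing |diff| at fixed t (hence fixed p) can
        # only increase the modified statistic
        table, _ = _classified_table(seed=12, n_proteins=300, n_interactors=10)
        spec = table.cutoffs["SigB"]
        k = float(table.data["se"].mean())
        d = table.data["diff"].to_numpy()
        se = table.data["se"].to_numpy()
        t = d / se
        for scale in (1.5, 3.0):
            before = np.abs(d / (se + spec.s0 * k))
            after = np.abs((scale * d) / (scale * d / t + spec.s0 * k))
            assert np.all(after >= before - 1e-12)

    def test_pure_null_discovery_rate_bounded(self):
        # no spiked effects: discoveries should be rare in every class
        table, _ = _classified_table(seed=13, n_proteins=800, n_interactors=0,
                                     bystander_frac=0.0)
        for name in ("SigA", "SigB", "SigC"):
            rate = len(table.significant(name) | table.significant(name, "depleted")) / 800
            assert rate <= table.cutoffs[name].fdr + 0.02

    def test_spiked_interactors_recovered(self):
        table, truth = _classified_table(seed=14, n_proteins=500, n_interactors=20,
                                         effect=4.0)
        recovered = table.significant("SigB") & truth.interactors
        assert len(recovered) / 20 >= 0.9

    def test_too_few_permutations_rejected(self):
        design = default_design()
        matrix, _ = simulate_lfq(design=design, n_proteins=50, seed=0)
        imputed = log_transform(matrix)
        table = two_sample_ttest(imputed, design.by_group("bait", "bait1"),
                                 design.by_group("wt_control"))
        with pytest.raises(ValueError, match="permutation"):
            classify_significance(table, imputed, DEFAULT_CUTOFFS, 5, seed=0)

    def test_tiny_groups_cannot_permute(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 4)),
                              index=[f"P{i}" for i in range(10)],
                              columns=list("abcd"))
        matrix = LfqMatrix(values, log_transformed=True)
        table = two_sample_ttest(matrix, ["a", "b"], ["c", "d"])
        # 2v2 can permute; 1v1 cannot even form a test, so shrink to the
        # smallest infeasible case via a doctored table
        table.group_a, table.group_b = ("a",), ("b",)
        with pytest.raises(ValueError, match="permute"):
            classify_significance(table, matrix, [SIG_B], 50, seed=0)


def test_volcano_plot_writes_panel_per_bait(tmp_path):
    table, _ = _classified_table(seed=15, n_proteins=100, n_interactors=5)
    out = tmp_path / "hawaii.png"
    from decaplex.volcano import plot_volcano

    plot_volcano({"bait1": table, "bait2": table}, out,
                 highlight=set(table.data.index[:2]))
    assert out.stat().st_size > 0


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

class TestPearson:
    def _table(self, diffs):
        data = pd.DataFrame({"diff": diffs, "se": 1.0, "p": 0.5, "neglog10p": 0.3,
                             "ratio": 1.0},
                            index=[f"P{i}" for i in range(len(diffs))])
        from decaplex.volcano import VolcanoTable
        return VolcanoTable(data=data, group_a=("a",), group_b=("b",))

    def test_self_correlation_is_one(self):
        t = self._table([1.0, 2.0, 3.0, 5.0])
        assert pearson_between(t, t) == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = self._table([1.0, 2.0, 3.0, 5.0])
        y = self._table([-1.0, -2.0, -3.0, -5.0])
        assert pearson_between(x, y) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(6)
        xv, yv = rng.normal(size=10), rng.normal(size=10)
        r = pearson_between(self._table(xv), self._table(yv))
        expected = (((xv - xv.mean()) * (yv - yv.mean())).sum()
                    / np.sqrt(((xv - xv.mean()) ** 2).sum()
                              * ((yv - yv.mean()) ** 2).sum()))
        assert r == pytest.approx(expected, rel=1e-12)

    def test_small_subset_rejected(self):
        t = self._table([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="3"):
            pearson_between(t, t, subset=["P0", "P1"])
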