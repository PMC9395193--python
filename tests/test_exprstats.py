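"""Expression statistics: quantile normalization, Welch test, FDR, calls, ΔΔCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from raydisp import (
    AnalysisError,
    ExpressionDataset,
    ValidationError,
    adaptive_bh,
    bh_adjust,
    ddct_relative_expression,
    de_table,
    generate_ct_table,
    generate_expression_dataset,
    quantile_normalize,
    quantile_normalize_matrix,
    welch_test,
)
from raydisp.datatypes import DEConfig


def _brute_force_bh(p):
    """Step-up BH adjusted p-values computed by direct enumeration."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    for pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


class TestQuantileNormalize:
    def test_two_column_oracle(self):
        out = quantile_normalize_matrix(np.array([[1, 4], [2, 5], [3, 6]], float))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert out == pytest.approx(expected)

    def test_identical_columns_fixed_point(self):
        x = np.tile(np.array([[3.0], [1.0], [2.0]]), (1, 4))
        assert quantile_normalize_matrix(x) == pytest.approx(x)

    def test_sorted_columns_identical_and_mean_preserved(self, rng):
        x = rng.lognormal(size=(200, 5))
        out = quantile_normalize_matrix(x)
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            assert np.array_equal(np.sort(out[:, j]), ref)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-9)

    def test_matches_mean_of_sorted_oracle_without_ties(self, rng):
        x = rng.uniform(1, 100, size=(50, 4))
        out = quantile_normalize_matrix(x)
        oracle = np.sort(x, axis=0).mean(axis=1)
        for j in range(4):
            assert out[np.argsort(x[:, j]), j] == pytest.approx(oracle)

    def test_ties_get_mean_of_spanned_targets(self):
        x = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize_matrix(x)
        ref = np.sort(x, axis=0).mean(axis=1)  # (5.5, 10.5, 17.5)
        assert out[0, 0] == out[1, 0] == pytest.approx(ref[:2].mean())
        assert out[2, 0] == pytest.approx(ref[2])

    def test_single_column_rejected(self):
        with pytest.raises(ValidationError, match="2 samples"):
            quantile_normalize_matrix(np.ones((5, 1)))

    def test_dataset_wrapper_preserves_metadata(self):
        ds, _ = generate_expression_dataset(20, seed=0)
        out = quantile_normalize(ds)
        assert out.gene_ids == ds.gene_ids
        assert out.group_labels == ds.group_labels


class TestWelch:
    def test_textbook_example(self):
        t, df, p = welch_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_identical_groups(self):
        t, _, p = welch_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_swap_flips_t_keeps_p(self, rng):
        x, y = rng.normal(size=5), rng.normal(1, 2, size=7)
        t1, df1, p1 = welch_test(x, y)
        t2, df2, p2 = welch_test(y, x)
        assert t2 == pytest.approx(-t1)
        assert (df2, p2) == (pytest.approx(df1), pytest.approx(p1))

    def test_agrees_with_scipy_on_random_instances(self, rng):
        for _ in range(300):
            nx, ny = rng.integers(2, 9, size=2)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=nx)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=ny)
            t, df, p = welch_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert df == pytest.approx(ref.df, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_variance_with_different_means(self):
        with pytest.raises(AnalysisError, match="degenerate-variance"):
            welch_test([1.0, 1.0], [2.0, 2.0])


class TestFdrAdjustment:
    def test_plain_bh_matches_brute_force_oracle(self):
        p = [0.01, 0.02, 0.04, 0.5]
        assert bh_adjust(p) == pytest.approx([0.04, 0.04, 0.0533333333, 0.5])
        assert bh_adjust(p) == pytest.approx(_brute_force_bh(p))

    @given(
        st.lists(st.floats(1e-6, 1.0, exclude_min=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100, derandomize=True)
    def test_bh_matches_brute_force_on_random_inputs(self, p):
        assert bh_adjust(p) == pytest.approx(_brute_force_bh(p), abs=1e-12)

    def test_all_p_one_rejects_nothing(self):
        _, reject = adaptive_bh([1.0] * 8, alpha=0.05)
        assert not reject.any()

    def test_small_p_rejects_everything(self):
        _, reject = adaptive_bh([0.001] * 10, alpha=0.05)
        assert reject.all()

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=100, derandomize=True)
    def test_adaptive_rejects_superset_of_plain_bh(self, p, alpha):
        p_adapt, reject_adapt = adaptive_bh(p, alpha)
        reject_plain = bh_adjust(p) <= alpha
        assert np.all(reject_adapt | ~reject_plain)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=80, derandomize=True)
    def test_adaptive_matches_described_procedure_brute_force(self, p):
        # independent re-derivation: first-pass BH at alpha/(1+alpha)
        # estimates m0; second pass scales BH-adjusted values by m0/m
        alpha = 0.05
        ours, _ = adaptive_bh(p, alpha)
        bh = _brute_force_bh(p)
        m = len(p)
        m0 = m - int(np.sum(bh <= alpha / (1 + alpha)))
        expected = np.clip(bh * m0 / m, 0.0, 1.0)
        assert ours == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=60, derandomize=True)
    def test_rejections_between_statsmodels_two_stage_variants(self, p):
        # the m0/m-scaled procedure sits between statsmodels' tsbky (which
        # multiplies by 1+alpha) and tsbh (which estimates m0 at level alpha)
        _, ours = adaptive_bh(p, 0.05)
        tsbky = multipletests(p, alpha=0.05, method="fdr_tsbky")[0]
        tsbh = multipletests(p, alpha=0.05, method="fdr_tsbh")[0]
        assert np.all(ours | ~tsbky)  # rejects at least what tsbky rejects
        assert np.all(tsbh | ~ours)  # and at most what tsbh rejects

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError, match="p_values"):
            adaptive_bh([0.0, 0.5])


class TestDeTable:
    def test_clear_effect_calls_match_planted_away_from_tails(self):
        # quantile normalization distorts the extreme tails of the common
        # distribution, so exact call recovery is asserted on interior genes
        ds, truth = generate_expression_dataset(
            1000, effect_log2=2.5, noise_sd=0.1, frac_up=0.1, frac_down=0.1, seed=2
        )
        table = de_table(ds)
        called = table["call"].to_numpy()
        expected = np.where(
            truth.planted_de_labels == "null", "ns", truth.planted_de_labels
        )
        baseline = np.log2(ds.intensities[:, :3].mean(axis=1))
        interior = (baseline > 7.0) & (baseline < 11.0)
        assert interior.sum() > 500
        assert np.array_equal(called[interior], expected[interior])

    def test_significant_but_small_fold_change_is_ns(self):
        # planted shift of 0.5 log2 units with tiny noise: significant
        # p-values, but |log2FC| < 1 keeps every call at "ns"
        ds, truth = generate_expression_dataset(
            1000, effect_log2=0.5, noise_sd=0.02, frac_up=0.2, frac_down=0.0, seed=3
        )
        table = de_table(ds)
        planted = truth.planted_de_labels == "up"
        assert (table["p_adjusted"].to_numpy()[planted] < 0.05).mean() > 0.9
        assert np.abs(table["log2fc"].to_numpy()[planted]).max() < 1.0
        assert (table["call"] == "ns").all()

    def test_log2fc_sign_follows_treatment_minus_reference(self):
        ds, truth = generate_expression_dataset(
            200, effect_log2=4.0, noise_sd=0.1, frac_up=0.1, frac_down=0.0, seed=5
        )
        table = de_table(ds)
        up = truth.planted_de_labels == "up"
        assert (table["log2fc"].to_numpy()[up] > 0).all()

    def test_null_pvalues_approximately_uniform(self):
        ds, _ = generate_expression_dataset(
            5000, frac_up=0.0, frac_down=0.0, effect_log2=0.0, seed=11
        )
        table = de_table(ds)
        ks = sps.kstest(table["p"], "uniform").statistic
        assert ks < 0.05


class TestDdct:
    def test_identical_conditions_fold_one(self):
        rows = []
        for cond in ("control", "treated"):
            for s in range(2):
                rows += [
                    {"sample_id": f"{cond}{s}", "condition": cond, "gene": "tg", "ct": 24.0},
                    {"sample_id": f"{cond}{s}", "condition": cond, "gene": "ef1a", "ct": 18.0},
                ]
        out = ddct_relative_expression(pd.DataFrame(rows), "control")
        assert out["fold"].to_numpy() == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles(self):
        rows = []
        for cond, ct in (("control", 24.0), ("treated", 23.0)):
            rows += [
                {"sample_id": cond, "condition": cond, "gene": "tg", "ct": ct},
                {"sample_id": cond, "condition": cond, "gene": "tg", "ct": ct},
                {"sample_id": cond, "condition": cond, "gene": "ef1a", "ct": 18.0},
                {"sample_id": cond, "condition": cond, "gene": "ef1a", "ct": 18.0},
            ]
        out = ddct_relative_expression(pd.DataFrame(rows), "control")
        fold = out.loc[out.condition == "treated", "fold"].iloc[0]
        assert fold == pytest.approx(2.0)

    def test_generator_roundtrip_fold_four(self):
        table, _ = generate_ct_table(["tg"], {"tg": 4.0}, ct_noise_sd=0.0, seed=1)
        out = ddct_relative_expression(table, "control")
        assert out.loc[out.condition == "treated", "fold"].iloc[0] == pytest.approx(4.0)

    def test_fold_monotone_decreasing_in_ddct(self):
        folds = []
        for planted in (0.5, 1.0, 2.0, 8.0):
            table, _ = generate_ct_table(["tg"], {"tg": planted}, ct_noise_sd=0.0, seed=1)
            out = ddct_relative_expression(table, "control")
            row = out[out.condition == "treated"].iloc[0]
            folds.append((row["ddct"], row["fold"]))
        folds.sort()
        values = [f for _, f in folds]
        assert values == sorted(values, reverse=True)

    def test_missing_reference_names_sample(self):
        df = pd.DataFrame(
            [
                {"sample_id": "s1", "condition": "control", "gene": "tg", "ct": 24.0},
                {"sample_id": "s1", "condition": "control", "gene": "ef1a", "ct": 18.0},
                {"sample_id": "s2", "condition": "treated", "gene": "tg", "ct": 23.0},
            ]
        )
        with pytest.raises(ValidationError, match="s2"):
            ddct_relative_expression(df, "control")


class TestExpressionDatasetValidation:
    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            ExpressionDataset(["g1"], np.array([[1.0, 0.0, 1.0, 1.0]]), ["a", "a", "b", "b"])

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError, match="two levels"):
            ExpressionDataset(["g1"], np.ones((1, 4)), ["a", "a", "a", "a"])

    def test_duplicate_gene_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicates"):
            ExpressionDataset(["g1", "g1"], np.ones((2, 4)), ["a", "a", "b", "b"])
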