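"""Expression correlation, subgenome bias, NB Wald divergence calling,
silent/suppressed scans, and rate-expression concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allodiverge.core_model import ExpressionMatrix, GeneRecord
from allodiverge.expression_analysis import (
    deceleration_expression_association,
    expression_divergence_call,
    normalize_expression_ratios,
    rate_expression_concordance,
    silent_copy_scan,
    size_factors,
    spearman_correlation_matrix,
    subgenome_bias_test,
    suppressed_region_scan,
)


def series(vals, prefix="g"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestSpearmanMatrix:
    def test_self_correlation_is_one(self):
        x = series([3.0, 1.0, 4.0, 1.5])
        m = spearman_correlation_matrix({"a": x, "b": x.copy()})
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        x = series([1.0, 2.0, 3.0, 4.0])
        m = spearman_correlation_matrix({"a": x, "b": x.iloc[::-1].set_axis(x.index)})
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_small_worked_example(self):
        m = spearman_correlation_matrix(
            {"x": series([1, 2, 3, 4]), "y": series([1, 3, 2, 4])}
        )
        assert m.loc["x", "y"] == pytest.approx(0.8)

    def test_restricted_to_shared_groups_and_minimum(self):
        x = series([1.0, 2.0, 3.0, 4.0])
        y = series([1.0, 2.0], prefix="g")  # shares only g0, g1
        with pytest.raises(ValueError, match=">=3 shared"):
            spearman_correlation_matrix({"a": x, "b": y})

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        x = series(rng.random(50))
        y = series(rng.random(50))
        base = spearman_correlation_matrix({"a": x, "b": y}).loc["a", "b"]
        for f in (np.exp, lambda v: v * 1000.0):
            m = spearman_correlation_matrix({"a": x.apply(f), "b": y})
            assert m.loc["a", "b"] == pytest.approx(base)


class TestBiasTest:
    def test_identical_pairs_give_p_one(self):
        a = np.arange(1.0, 21.0)
        with pytest.warns(UserWarning, match="zero"):
            out = subgenome_bias_test(a, a.copy())
        assert out["two_copy_p"] == 1.0

    def test_shifted_pairs_strongly_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(1.0, 0.5, 100)
        out = subgenome_bias_test(a + 1.0, a)
        assert out["two_copy_p"] < 1e-6

    def test_single_copy_null_pvalues_uniformish(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(100):
            a, b = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
            ps.append(subgenome_bias_test(
                rng.normal(0, 1, 20), rng.normal(0, 1, 20), a, b
            )["single_copy_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDivergenceCall:
    def _counts(self, mat, n_samples):
        cols = [f"h.log.rep{i + 1}" for i in range(n_samples)]
        return pd.DataFrame(mat, columns=cols,
                            index=[f"g{i}" for i in range(len(mat))])

    def _make(self, rng, n_pairs, mu, shift_idx=(), fold=10.0, disp=0.05, reps=2):
        size = 1.0 / disp
        rows, names = [], []
        for i in range(n_pairs):
            mu_a = mu[i] * (fold if i in set(shift_idx) else 1.0)
            rows.append(rng.negative_binomial(size, size / (size + mu_a), reps))
            names.append(f"p{i}a")
            rows.append(rng.negative_binomial(size, size / (size + mu[i]), reps))
            names.append(f"p{i}b")
        counts = pd.DataFrame(np.vstack(rows), index=names,
                              columns=[f"h.log.rep{j + 1}" for j in range(reps)])
        pairs = pd.DataFrame(
            {
                "group_id": [f"p{i}" for i in range(n_pairs)],
                "gene_a": [f"p{i}a" for i in range(n_pairs)],
                "gene_b": [f"p{i}b" for i in range(n_pairs)],
            }
        )
        return counts, pairs

    def test_equal_counts_not_divergent(self):
        counts = self._counts(np.tile([[100, 120]], (10, 1)), 2)
        pairs = pd.DataFrame(
            {"group_id": ["x"], "gene_a": ["g0"], "gene_b": ["g1"]}
        )
        out, _ = expression_divergence_call(counts, pairs)
        assert out["fold"].iloc[0] == pytest.approx(1.0)
        assert not out["divergent"].iloc[0]

    def test_tenfold_shift_mostly_detected(self):
        rng = np.random.default_rng(4)
        mu = 10 ** rng.uniform(1.5, 3.0, 400)
        shifted = range(0, 80)
        counts, pairs = self._make(rng, 400, mu, shift_idx=shifted)
        out, _ = expression_divergence_call(counts, pairs)
        hit = out.loc[[i in set(shifted) for i in range(400)], "divergent"].mean()
        assert hit >= 0.8

    def test_null_false_call_rate_below_2_percent(self):
        rng = np.random.default_rng(5)
        mu = 10 ** rng.uniform(1.5, 3.0, 2000)
        counts, pairs = self._make(rng, 2000, mu)
        out, _ = expression_divergence_call(counts, pairs)
        assert out["divergent"].mean() <= 0.02

    def test_single_replicate_refused(self):
        counts = self._counts(np.array([[10], [12]]), 1)
        pairs = pd.DataFrame({"group_id": ["x"], "gene_a": ["g0"], "gene_b": ["g1"]})
        with pytest.raises(ValueError, match="ratio-only"):
            expression_divergence_call(counts, pairs)

    def test_size_factors_counter_library_depth(self):
        rng = np.random.default_rng(6)
        base = 10 ** rng.uniform(1, 3, 300)
        counts = pd.DataFrame(
            {"s1": base, "s2": base * 4.0}, index=[f"g{i}" for i in range(300)]
        )
        sf = size_factors(counts)
        assert sf["s2"] / sf["s1"] == pytest.approx(4.0, rel=1e-6)


class TestRatioNormalization:
    def test_median_scaled_to_one(self):
        out, c = normalize_expression_ratios([2.0, 4.0, 8.0])
        assert c == pytest.approx(4.0)
        assert np.median(out) == pytest.approx(1.0)

    def test_already_centered(self):
        out, c = normalize_expression_ratios([0.5, 1.0, 2.0])
        assert c == 1.0

    def test_zero_ratios_retained(self):
        out, c = normalize_expression_ratios([2.0, 0.0])
        assert c == 2.0 and out[1] == 0.0


class TestConcordance:
    def _tables(self, rng, n=400, n_div_rate=30, n_div_expr=40, same=False):
        gids = [f"p{i}" for i in range(n)]
        rate = pd.DataFrame(
            {
                "group_id": gids,
                "omega_a": rng.lognormal(0, 0.4, n),
                "omega_b": rng.lognormal(0, 0.4, n),
                "divergent": [i < n_div_rate for i in range(n)],
            }
        )
        expr_div = (
            [i < n_div_rate for i in range(n)]
            if same
            else [i >= n - n_div_expr for i in range(n)]
        )
        expr = pd.DataFrame(
            {
                "group_id": gids,
                "ratio_normalized": rng.lognormal(0, 0.5, n),
                "divergent": expr_div,
            }
        )
        return rate, expr

    def test_identical_sets_overlap_significant(self):
        rng = np.random.default_rng(7)
        rate, expr = self._tables(rng, n=4000, n_div_rate=50, same=True)
        out = rate_expression_concordance(rate, expr)
        assert out["overlap_p"] < 1e-20
        assert out["n_both"] == 50

    def test_empty_divergent_sets(self):
        rng = np.random.default_rng(8)
        rate, expr = self._tables(rng, n_div_rate=0, n_div_expr=0)
        out = rate_expression_concordance(rate, expr)
        assert out["overlap_p"] == 1.0
        assert np.isfinite(out["spearman_rho"])

    def test_independent_sets_p_uniform_over_seeds(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            n = 500
            gids = [f"p{i}" for i in range(n)]
            rate_set = rng.choice(n, 40, replace=False)
            expr_set = rng.choice(n, 60, replace=False)
            rate = pd.DataFrame(
                {"group_id": gids, "omega_a": rng.lognormal(0, 0.3, n),
                 "omega_b": rng.lognormal(0, 0.3, n),
                 "divergent": np.isin(np.arange(n), rate_set)}
            )
            expr = pd.DataFrame(
                {"group_id": gids, "ratio_normalized": rng.lognormal(0, 0.3, n),
                 "divergent": np.isin(np.arange(n), expr_set)}
            )
            ps.append(rate_expression_concordance(rate, expr)["overlap_p"])
        # conservative-discrete, but far from anti-conservative
        assert np.mean(np.array(ps) <= 0.01) <= 0.03


class TestDecelerationAssociation:
    def test_identical_classes_null(self):
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            expr = rng.normal(1.0, 0.5, 300)
            dec = np.zeros(300, bool)
            dec[rng.choice(300, 60, replace=False)] = True
            ps.append(deceleration_expression_association(dec, expr)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_class_detected(self):
        rng = np.random.default_rng(9)
        expr = rng.normal(1.0, 0.5, 400)
        dec = np.arange(400) < 200
        expr[dec] += 0.5
        out = deceleration_expression_association(dec, expr)
        assert out["p"] < 1e-4
        assert out["median_decelerated"] > out["median_other"]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            deceleration_expression_association([True, True], [1.0, 2.0])


def _expr_matrix(df):
    meta = pd.DataFrame(
        {
            "species": ["hyb"] * len(df.columns),
            "condition": ["log"] * len(df.columns),
            "replicate": range(1, len(df.columns) + 1),
        },
        index=df.columns,
    )
    return ExpressionMatrix(df, meta, "fpkm")


class TestSilentCopyScan:
    def test_silent_copy_with_low_partner_flag(self):
        df = pd.DataFrame(
            {
                "s1": [0.0, 0.6], "s2": [0.0, 0.5],
                "s3": [0.0, 0.7], "s4": [0.0, 0.6],
            },
            index=["b_copy", "a_copy"],
        )
        pairs = pd.DataFrame(
            {"group_id": ["p1"], "gene_a": ["a_copy"], "gene_b": ["b_copy"]}
        )
        out = silent_copy_scan(pairs, _expr_matrix(df))
        assert len(out) == 1
        assert out.iloc[0]["silent_copy"] == "B"
        assert out.iloc[0]["low_partner"]

    def test_partial_zeros_not_silent(self):
        df = pd.DataFrame(
            {"s1": [0.0, 5.0], "s2": [0.0, 5.0], "s3": [0.1, 5.0], "s4": [0.0, 5.0]},
            index=["b_copy", "a_copy"],
        )
        pairs = pd.DataFrame(
            {"group_id": ["p1"], "gene_a": ["a_copy"], "gene_b": ["b_copy"]}
        )
        assert silent_copy_scan(pairs, _expr_matrix(df)).empty

    def test_no_silent_copies(self):
        df = pd.DataFrame({"s1": [1.0, 2.0]}, index=["a", "b"])
        pairs = pd.DataFrame({"group_id": ["p"], "gene_a": ["a"], "gene_b": ["b"]})
        assert silent_copy_scan(pairs, _expr_matrix(df)).empty


class TestSuppressedRegionScan:
    def _genes(self, scaffold, n, spacing=5000):
        return [
            GeneRecord(f"{scaffold}.g{i}", "hyb", scaffold,
                       i * spacing, i * spacing + 1000)
            for i in range(n)
        ]

    def test_uniform_expression_yields_nothing(self):
        genes = self._genes("s1", 200)
        expr = {g.gene_id: 1.0 for g in genes}
        assert suppressed_region_scan(genes, expr).empty

    def test_low_block_found_as_single_region(self):
        genes = self._genes("s1", 400)
        expr = {g.gene_id: 2.0 for g in genes}
        block = genes[100:150]  # 50-gene block at 1/100 of baseline
        for g in block:
            expr[g.gene_id] = 0.0
        out = suppressed_region_scan(genes, expr)
        assert len(out) == 1
        start, end = out.iloc[0]["start"], out.iloc[0]["end"]
        assert start <= block[0].start and end >= block[-1].end

    def test_min_genes_larger_than_any_window(self):
        genes = self._genes("s1", 50)
        expr = {g.gene_id: 1.0 for g in genes}
        assert suppressed_region_scan(genes, expr, min_genes=1000).empty
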