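"""Ks filtering, expression-bias classes, interaction statistics and the
colocalization machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wgdhic import (ConfigurationError, DataError, TransColocModel,
                    classify_expression_bias, colocalization_conservation,
                    colocalization_test, compare_bias_vs_interaction,
                    filter_wgd_paralogs, interaction_score,
                    methylation_similarity, pair_interaction_frequency,
                    randomization_null)
from wgdhic._stats import benjamini_hochberg
from wgdhic.comparative import OrthologTable

from conftest import make_matrix


def binom_tail_oracle(x, n, p):
    """Exact upper-tail binomial probability by direct summation."""
    return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k)
               for k in range(x, n + 1))


def bh_oracle(pvals):
    """Brute-force step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestKsFilter:
    def test_window_inclusive(self):
        pairs = pd.DataFrame({"gene1": list("abcd"), "gene2": list("wxyz"),
                              "ks": [0.3, 0.7, 0.05, 0.6]})
        kept = filter_wgd_paralogs(pairs)
        assert kept["ks"].tolist() == [0.3, 0.05, 0.6]

    def test_bad_ks_rejected(self):
        with pytest.raises(DataError):
            filter_wgd_paralogs(pd.DataFrame({"ks": [-0.1]}))
        with pytest.raises(DataError):
            filter_wgd_paralogs(pd.DataFrame({"ks": [np.nan]}))


class TestExpressionBias:
    @pytest.mark.parametrize("t1,t2,expected", [
        (10.0, 4.0, "biased"),
        (10.0, 6.0, "similar"),
        (0.4, 8.0, "excluded"),
        (10.0, 5.0, "similar"),   # exactly twofold is not "more than twofold"
    ])
    def test_classes(self, t1, t2, expected):
        assert classify_expression_bias(t1, t2) == expected

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1e4), st.floats(0.0, 1e4))
    def test_symmetric(self, t1, t2):
        assert classify_expression_bias(t1, t2) == classify_expression_bias(t2, t1)

    def test_negative_rejected(self):
        with pytest.raises(DataError):
            classify_expression_bias(-1.0, 2.0)


def two_chrom_matrix(block, state="raw", mask=None):
    """Two chromosomes whose trans block is given; cis left empty."""
    n1, n2 = block.shape
    dense = np.zeros((n1 + n2, n1 + n2))
    dense[:n1, n1:] = block
    dense[n1:, :n1] = block.T
    return make_matrix(dense, state=state,
                       chrom_sizes={"chr1": n1 * 10_000, "chr2": n2 * 10_000},
                       mask=mask)


class TestPairStatistics:
    def test_interaction_frequency_conventions(self):
        block = np.zeros((3, 3))
        block[0, 1] = 7.0
        mask = np.zeros(6, bool)
        mask[2] = True
        M = two_chrom_matrix(block, state="ice", mask=mask)
        assert pair_interaction_frequency(M, 0, 4) == 7.0
        assert pair_interaction_frequency(M, 1, 5) == 0.0   # unstored
        assert np.isnan(pair_interaction_frequency(M, 2, 3))  # masked
        with pytest.raises(DataError):
            pair_interaction_frequency(M, 0, 1)  # same chromosome

    def test_interaction_score_row_means(self):
        dense = np.zeros((5, 5))
        dense[0, 2], dense[0, 3], dense[0, 4] = 0.5, 1.5, 1.0
        dense = dense + dense.T
        M = make_matrix(dense, state="oe")
        assert interaction_score(M, 0) == 1.0
        ones = make_matrix(np.ones((5, 5)), state="oe")
        assert interaction_score(ones, 2) == 1.0
        masked = make_matrix(dense, state="oe",
                             mask=np.array([True] + [False] * 4))
        assert np.isnan(interaction_score(masked, 0))

    def test_score_excludes_near_diagonal(self):
        dense = np.zeros((4, 4))
        dense[0, 1] = dense[1, 0] = 100.0  # inside the excluded band
        dense[0, 2] = dense[2, 0] = 2.0
        dense[0, 3] = dense[3, 0] = 4.0
        M = make_matrix(dense, state="oe")
        assert interaction_score(M, 0) == 3.0


class TestColocalization:
    def test_pvalues_match_exact_tail_oracle(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 4, (6, 6)).astype(float)
        block[0, 0] = 9.0
        M = two_chrom_matrix(block)
        model = TransColocModel(M)
        n = int(block.sum())
        pairs = [(0, 6), (2, 8), (5, 11)]
        p = model.pvalues([a for a, _ in pairs], [b for _, b in pairs])
        for (b1, b2), got in zip(pairs, p):
            i, j = b1, b2 - 6
            p0 = block.sum(axis=1)[i] * block.sum(axis=0)[j] / n**2
            x = int(block[i, j])
            want = binom_tail_oracle(x, n, p0) if x > 0 else 1.0
            assert abs(got - want) < 1e-12

    def test_uniform_marginals_example(self):
        # near-uniform 10x10 block: every entry 1 except one pair with 5;
        # oracle recomputes p0 and the tail sum from the block itself
        block = np.ones((10, 10))
        block[0, 0] = 5.0
        M = two_chrom_matrix(block)
        p = TransColocModel(M).pvalues([0], [10])[0]
        n = int(block.sum())
        p0 = block.sum(axis=1)[0] * block.sum(axis=0)[0] / n**2
        assert abs(p - binom_tail_oracle(5, n, p0)) < 1e-12

    def test_zero_count_never_colocalized(self):
        block = np.ones((4, 4))
        block[1, 1] = 0.0
        M = two_chrom_matrix(block)
        pairs = pd.DataFrame({"bin1": [1], "bin2": [5]})
        out = colocalization_test(M, pairs)
        assert out["coloc_p"].iloc[0] == 1.0
        assert not out["colocalized"].iloc[0]

    def test_non_integer_counts_rejected(self):
        M = two_chrom_matrix(np.full((3, 3), 1.5))
        with pytest.raises(DataError):
            TransColocModel(M)

    def test_same_chromosome_pairs_rejected(self):
        M = two_chrom_matrix(np.ones((3, 3)))
        with pytest.raises(DataError):
            TransColocModel(M).pvalues([0], [1])

    def test_bh_matches_step_up_oracle(self):
        p = np.array([0.001] * 10 + [0.5] * 90)
        adj = benjamini_hochberg(p)
        assert np.allclose(adj, bh_oracle(p))
        assert ((adj < 0.05) == (p == 0.001)).all()
        rng = np.random.default_rng(1)
        for _ in range(5):
            p = rng.uniform(0, 1, 40)
            assert np.allclose(benjamini_hochberg(p), bh_oracle(p))


class TestRandomizationNull:
    def _genes(self, n_per_chrom=8):
        rows = []
        for c, off in (("chr1", 0), ("chr2", 10)):
            for k in range(n_per_chrom):
                rows.append((f"{c}_g{k}", c, off + k))
        return pd.DataFrame(rows, columns=["gene", "chrom", "bin"])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        M = two_chrom_matrix(rng.poisson(3.0, (10, 10)).astype(float))
        genes = self._genes()
        a = randomization_null(10, genes, M, reps=20, seed=42)
        b = randomization_null(10, genes, M, reps=20, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_bad_config_rejected(self):
        M = two_chrom_matrix(np.ones((3, 3)))
        with pytest.raises(ConfigurationError):
            randomization_null(5, self._genes(), M, reps=0, seed=1)
        with pytest.raises(ConfigurationError):
            randomization_null(0, self._genes(), M, reps=5, seed=1)


class TestBiasVsInteraction:
    def _table(self, bias_classes, freqs):
        n = len(bias_classes)
        return pd.DataFrame({
            "bias_class": bias_classes, "inter_freq": freqs,
            "tpm1": np.linspace(1, 10, n), "tpm2": np.linspace(10, 1, n),
            "score1": np.linspace(0.5, 2.0, n), "score2": np.linspace(2.0, 0.5, n),
        })

    def test_planted_direction(self):
        rng = np.random.default_rng(0)
        classes = ["biased"] * 30 + ["similar"] * 30
        freqs = np.concatenate([rng.normal(1.0, 0.1, 30),
                                rng.normal(2.0, 0.1, 30)])
        out = compare_bias_vs_interaction(self._table(classes, freqs))
        res = out["freq_biased_vs_similar"]
        assert res.pvalue < 0.01 and res.direction == "biased<similar"

    def test_all_biased_degenerate(self):
        out = compare_bias_vs_interaction(
            self._table(["biased"] * 8, np.arange(8.0)))
        assert "error" in out["freq_biased_vs_similar"]
        assert out["score_high_vs_low_copy"].n1 == 8


class TestMethylationSimilarity:
    def _pairs(self, n_cc=20, n_nc=60, seed=0):
        rng = np.random.default_rng(seed)
        rows, meth = [], {}
        for k in range(n_cc + n_nc):
            g1, g2 = f"p{k}_1", f"p{k}_2"
            base = rng.uniform(0.2, 0.8)
            if k < n_cc:
                d = abs(rng.normal(0, 0.03))
            else:
                d = abs(rng.normal(0, 0.25))
            meth[g1] = np.clip(base, 0, 1)
            meth[g2] = np.clip(base + d, 0, 1)
            rows.append((g1, g2, k < n_cc))
        table = pd.DataFrame(rows, columns=["gene1", "gene2", "colocalized"])
        mdf = pd.DataFrame({"gene": list(meth),
                            "cg": list(meth.values()),
                            "chg": list(meth.values()),
                            "chh": list(meth.values())}).set_index("gene")
        return table, mdf

    def test_planted_similarity(self):
        table, meth = self._pairs()
        out = methylation_similarity(table, meth)
        for ctx in ("cg", "chg", "chh"):
            assert out[ctx].pvalue < 0.01
            assert out[ctx].direction == "colocalized<noncolocalized"

    def test_missing_context_named(self):
        table, meth = self._pairs(5, 10)
        with pytest.raises(DataError, match="chh"):
            methylation_similarity(table, meth.drop(columns=["chh"]))

    def test_out_of_range_level_rejected(self):
        table, meth = self._pairs(5, 10)
        meth.iloc[0, 0] = 1.5
        with pytest.raises(DataError):
            methylation_similarity(table, meth)


class TestColocConservation:
    def test_identity_full_overlap(self):
        pairs = [("a1", "a2"), ("a3", "a4")]
        orth = OrthologTable(pd.DataFrame(
            {"gene_a": ["a1", "a2", "a3", "a4"],
             "gene_b": ["b1", "b2", "b3", "b4"]}))
        res = colocalization_conservation(
            pairs, [("b1", "b2"), ("b3", "b4")], orth, n_universe=100)
        assert res["overlap_n"] == 2
        assert res["frac_a"] == res["frac_b"] == 1.0

    def test_disjoint_sets(self):
        orth = OrthologTable(pd.DataFrame(
            {"gene_a": ["a1", "a2", "a3", "a4"],
             "gene_b": ["b1", "b2", "b3", "b4"]}))
        res = colocalization_conservation(
            [("a1", "a2")], [("b3", "b4")], orth, n_universe=100)
        assert res["overlap_n"] == 0

    def test_fisher_matches_hypergeometric_oracle(self):
        from scipy import stats
        # table (10 overlap, 90 A-only, 40 B-only, 860 neither)
        orth_rows = [(f"a{k}", f"b{k}") for k in range(300)]
        orth = OrthologTable(pd.DataFrame(orth_rows, columns=["gene_a", "gene_b"]))
        coloc_a = [(f"a{2*k}", f"a{2*k+1}") for k in range(100)]
        coloc_b = [(f"b{2*k}", f"b{2*k+1}") for k in range(10)] + \
                  [(f"b{200+2*k}", f"b{201+2*k}") for k in range(40)]
        res = colocalization_conservation(coloc_a, coloc_b, orth,
                                          n_universe=1000)
        p_obs = stats.hypergeom.pmf(10, 1000, 100, 50)
        oracle = sum(stats.hypergeom.pmf(k, 1000, 100, 50)
                     for k in range(0, 51)
                     if stats.hypergeom.pmf(k, 1000, 100, 50) <= p_obs * (1 + 1e-9))
        assert np.isclose(res["fisher_p"], oracle, rtol=1e-8)

    def test_empty_set_skips_test(self, caplog):
        orth = OrthologTable(pd.DataFrame({"gene_a": ["a1"], "gene_b": ["b1"]}))
        with caplog.at_level("WARNING"):
            res = colocalization_conservation([], [("b1", "b1")], orth,
                                              n_universe=10)
        assert res["frac_a"] == 0.0 and np.isnan(res["fisher_p"])
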