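"""Screen scoring: normalization, log2FC, alpha-RRA, permutation FDR, hits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medsift import screen_scoring as ss


def _table(guides, genes, **cols):
    df = pd.DataFrame({"gene": genes, **cols}, index=pd.Index(guides, name="guide_id"))
    df["is_control"] = [g == "non-targeting" for g in genes]
    return df


class TestTotalCountNormalize:
    def test_rescales_to_mean_total(self):
        tbl = _table(["g1", "g2"], ["A", "B"], s1=[40, 60], s2=[120, 180])
        out = ss.total_count_normalize(tbl, ["s1", "s2"])
        assert out["s1"].sum() == pytest.approx(200)
        assert out["s2"].sum() == pytest.approx(200)

    def test_equal_totals_unchanged(self):
        tbl = _table(["g1", "g2"], ["A", "B"], s1=[50, 50], s2=[30, 70])
        out = ss.total_count_normalize(tbl, ["s1", "s2"])
        pd.testing.assert_frame_equal(out, tbl.astype({"s1": float, "s2": float}))

    def test_single_sample_unchanged(self):
        tbl = _table(["g1"], ["A"], s1=[10])
        assert ss.total_count_normalize(tbl, ["s1"])["s1"].iloc[0] == 10

    def test_zero_column_named_in_error(self):
        tbl = _table(["g1"], ["A"], s1=[0], s2=[5])
        with pytest.raises(ValueError, match="s1"):
            ss.total_count_normalize(tbl, ["s1", "s2"])


class TestGuideLog2fc:
    def test_equal_columns_zero(self):
        tbl = _table(["g1", "g2"], ["A", "B"], s=[10, 20], ref=[10, 20])
        out = ss.guide_log2fc(tbl, "s", "ref")
        assert (out["log2fc"] == 0).all()

    def test_closed_form(self):
        tbl = _table(["g1"], ["A"], s=[31], ref=[7])
        assert ss.guide_log2fc(tbl, "s", "ref")["log2fc"].iloc[0] == pytest.approx(2.0)

    def test_rank_and_percentile_convention(self):
        tbl = _table(["g1", "g2", "g3"], ["A", "B", "C"], s=[100, 10, 1], ref=[1, 10, 100])
        out = ss.guide_log2fc(tbl, "s", "ref")
        assert out.loc["g1", "rank"] == 1
        assert out.loc["g1", "percentile"] == pytest.approx(1 / 3)
        assert sorted(out["rank"]) == [1, 2, 3]

    def test_stable_tie_break_by_row_order(self):
        tbl = _table(["b", "a"], ["B", "A"], s=[10, 10], ref=[10, 10])
        out = ss.guide_log2fc(tbl, "s", "ref")
        assert out.loc["b", "rank"] == 1 and out.loc["a", "rank"] == 2

    def test_missing_column_errors(self):
        tbl = _table(["g1"], ["A"], s=[1])
        with pytest.raises(ValueError):
            ss.guide_log2fc(tbl, "s", "nope")


class TestAlphaRra:
    def test_worked_case_alpha_one(self):
        """u = (0.1, 0.3): beta_1 = 1 - 0.9^2 = 0.19, beta_2 = 0.09, rho = 0.09."""
        rho = ss._rra_rho(np.array([0.1, 0.3]), 2, 1.0)
        assert rho == pytest.approx(0.09, abs=1e-12)

    def test_worked_case_alpha_truncated(self):
        """alpha = 0.2 admits only the first guide: rho = 0.19."""
        rho = ss._rra_rho(np.array([0.1, 0.3]), 2, 0.2)
        assert rho == pytest.approx(0.19, abs=1e-12)

    def test_worst_case(self):
        assert ss._rra_rho(np.array([1.0, 1.0, 1.0]), 3, 1.0) == 1.0

    def test_no_participating_guide(self):
        assert ss._rra_rho(np.array([0.5, 0.9]), 2, 0.25) == 1.0

    def test_monotone_in_percentiles(self):
        """Improving any participating percentile never increases rho."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            u = np.sort(rng.uniform(size=4))
            rho = ss._rra_rho(u, 4, 1.0)
            k = rng.integers(0, 4)
            u2 = u.copy()
            u2[k] *= rng.uniform()
            assert ss._rra_rho(u2, 4, 1.0) <= rho + 1e-15

    def test_guide_order_invariance(self):
        stats_tbl = pd.DataFrame(
            {"gene": ["A", "B", "A", "B"], "percentile": [0.1, 0.5, 0.4, 0.2],
             "is_control": False, "log2fc": [3, 1, 2, 2.5]},
            index=["g1", "g2", "g3", "g4"],
        )
        shuffled = stats_tbl.iloc[[2, 0, 3, 1]]
        pd.testing.assert_series_equal(
            ss.alpha_rra_score(stats_tbl, alpha=1.0), ss.alpha_rra_score(shuffled, alpha=1.0)
        )


class TestPermutationFdr:
    def test_extreme_gene_minimal_p(self):
        """A gene holding the best percentiles gets p = 1/(1 + n_perm)."""
        n = 40
        pct = np.arange(1, n + 1) / n
        genes = ["HIT"] * 4 + [f"G{i}" for i in range(n - 4)]
        tbl = pd.DataFrame({"gene": genes, "percentile": pct, "is_control": False,
                            "log2fc": -pct}, index=[f"g{i}" for i in range(n)])
        rho = ss.alpha_rra_score(tbl, alpha=1.0)
        out = ss.permutation_fdr(rho, tbl, n_perm=200, alpha=1.0, seed=0)
        assert out.loc["HIT", "p_perm"] == pytest.approx(1 / 201)

    def test_null_pvalues_uniform(self):
        """KS statistic of null-gene p-values vs U(0,1) below the 1% critical
        value (1.63 / sqrt(n) for n = 500 genes)."""
        rng = np.random.default_rng(42)
        n_genes, gpg = 500, 4
        n = n_genes * gpg
        pct = rng.permutation(np.arange(1, n + 1) / n)
        tbl = pd.DataFrame({
            "gene": np.repeat([f"G{i}" for i in range(n_genes)], gpg),
            "percentile": pct, "is_control": False, "log2fc": -pct,
        }, index=[f"g{i}" for i in range(n)])
        rho = ss.alpha_rra_score(tbl, alpha=1.0)
        out = ss.permutation_fdr(rho, tbl, n_perm=300, alpha=1.0, seed=1)
        ks = stats.kstest(out["p_perm"], "uniform").statistic
        assert ks < 1.63 / np.sqrt(n_genes)

    def test_matches_exhaustive_enumeration(self):
        """4-guide gene in an 8-guide library: permutation p agrees with full
        C(8,4) subset enumeration within 2 Monte-Carlo standard errors."""
        n, k = 8, 4
        pct = np.arange(1, n + 1) / n
        tbl = pd.DataFrame({
            "gene": ["A"] * k + [f"G{i}" for i in range(n - k)],
            "percentile": pct, "is_control": False, "log2fc": -pct,
        }, index=[f"g{i}" for i in range(n)])
        alpha = 1.0
        rho_obs = ss._rra_rho(pct[:k], k, alpha)
        null = [ss._rra_rho(np.array(c), k, alpha)
                for c in itertools.combinations(pct, k)]
        q_exact = np.mean([r <= rho_obs + 1e-15 for r in null])
        n_perm = 2000
        rho = ss.alpha_rra_score(tbl, alpha=alpha)
        out = ss.permutation_fdr(rho, tbl, n_perm=n_perm, alpha=alpha, seed=2)
        se = np.sqrt(q_exact * (1 - q_exact) / n_perm)
        assert abs(out.loc["A", "p_perm"] - q_exact) <= 2 * se + 2 / (n_perm + 1)

    def test_low_n_perm_rejected(self):
        with pytest.raises(ValueError, match="n_perm"):
            ss.permutation_fdr(pd.Series({"A": 0.5}), pd.DataFrame(), n_perm=50)

    def test_seed_determinism(self, small_screen):
        a = ss.score_condition(small_screen.counts, "low_0.01_6", n_perm=100, seed=9)
        b = ss.score_condition(small_screen.counts, "low_0.01_6", n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestGeneLfcAlphamean:
    def _tbl(self, pcts, lfcs):
        return pd.DataFrame({"gene": "A", "percentile": pcts, "log2fc": lfcs,
                             "is_control": False},
                            index=[f"g{i}" for i in range(len(pcts))])

    def test_all_pass_plain_mean(self):
        out = ss.gene_lfc_alphamean(self._tbl([0.1, 0.2], [1.0, 3.0]), alpha=0.25)
        assert out["A"] == pytest.approx(2.0)

    def test_filter_semantics(self):
        out = ss.gene_lfc_alphamean(self._tbl([0.1, 0.9], [2.0, 0.0]), alpha=0.25)
        assert out["A"] == pytest.approx(2.0)

    def test_fallback_mean_when_none_pass(self):
        out = ss.gene_lfc_alphamean(self._tbl([0.5, 0.9], [1.0, 3.0]), alpha=0.25)
        assert out["A"] == pytest.approx(2.0)


class TestSelectHits:
    def _tables(self, fdrs):
        return {f"c{i}": pd.Series({"A": f}) for i, f in enumerate(fdrs)}

    def test_primary_clause(self):
        out = ss.select_hits(self._tables([0.01, 0.9, 0.9, 0.9]))
        assert bool(out.loc["A", "is_hit"])

    def test_secondary_clause(self):
        out = ss.select_hits(self._tables([0.15, 0.18, 0.9, 0.9]))
        assert bool(out.loc["A", "is_hit"])

    def test_rule_complement(self):
        out = ss.select_hits(self._tables([0.15, 0.9, 0.9, 0.9]))
        assert not bool(out.loc["A", "is_hit"])

    def test_missing_entries_count_as_one(self):
        tables = {"c0": pd.Series({"A": 0.15, "B": 0.01}), "c1": pd.Series({"B": 0.5})}
        out = ss.select_hits(tables)
        assert not bool(out.loc["A", "is_hit"]) and bool(out.loc["B", "is_hit"])
        assert out.loc["A", "c1"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ss.select_hits({})


class TestControlEnrichment:
    def _stats(self, targeting, control):
        vals = np.concatenate([targeting, control])
        return pd.DataFrame({
            "gene": ["T"] * len(targeting) + ["non-targeting"] * len(control),
            "is_control": [False] * len(targeting) + [True] * len(control),
            "log2fc": vals,
        })

    def test_identical_distributions_z_near_zero(self, rng):
        x = rng.normal(size=200)
        out = ss.control_enrichment_summary(self._stats(x, x.copy()))
        assert abs(out["ranksum_z"]) < 1e-9

    def test_shifted_targeting_positive_z(self, rng):
        out = ss.control_enrichment_summary(
            self._stats(rng.normal(1.0, 1.0, 200), rng.normal(0.0, 1.0, 200)))
        assert out["ranksum_z"] > 3

    def test_small_case_against_exact_enumeration(self):
        """Rank-sum on a tiny case vs the exact Mann-Whitney distribution."""
        t, c = np.array([3.0, 5.0, 7.0]), np.array([1.0, 2.0, 4.0])
        out = ss.control_enrichment_summary(self._stats(t, c))
        # exhaustive oracle: U = #{(t_i, c_j): t_i > c_j} = 8 of 9; under the
        # null all C(6,3) = 20 rank assignments are equally likely and 4 of
        # them give |U - 4.5| >= 3.5, so the exact two-sided p is 0.2
        exact = stats.mannwhitneyu(t, c, alternative="two-sided", method="exact")
        assert exact.pvalue == pytest.approx(0.2, abs=1e-12)
        assert exact.statistic == 8.0
        # the summary's normal-approximation p sits near the exact value
        assert out["ranksum_p"] == pytest.approx(0.127, abs=0.001)
        assert out["ranksum_z"] > 0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ss.control_enrichment_summary(self._stats(np.array([1.0]), np.array([])))
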