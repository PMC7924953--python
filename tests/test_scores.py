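from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from depmix import (Source, crispr_shrna_inconsistency, efficacy,
                    essential_call_significance, fisher_overrepresentation,
                    gene_score_table, overlap_index, pc1_mixing_ratio,
                    selectivity_fit)
from depmix.scores import fisher_upper_tail

from conftest import small_matrix


def hypergeom_tail_oracle(a, b, c, d):
    """Exact one-sided Fisher p by rational-arithmetic enumeration."""
    r1, n1, N = a + b, a + c, a + b + c + d
    total = Fraction(0)
    for k in range(a, min(r1, n1) + 1):
        total += Fraction(comb(r1, k) * comb(N - r1, n1 - k), comb(N, n1))
    return float(total)


class TestEfficacy:
    def test_constant_row_any_percentile(self):
        m = small_matrix(np.full((1, 30), -0.7))
        for x in (1, 2.5, 25, 50, 99):
            assert efficacy(m, x).iloc[0] == pytest.approx(-0.7)

    def test_median_by_sorting_oracle(self):
        row = np.arange(1, 424, dtype=float)
        np.random.default_rng(0).shuffle(row)
        m = small_matrix(row.reshape(1, -1))
        assert efficacy(m, 50).iloc[0] == pytest.approx(212.0)

    def test_monotone_in_percentile(self, default_screens):
        m = default_screens["combined"]
        e1, e99 = efficacy(m, 1), efficacy(m, 99)
        ok = e1.notna()
        assert (e1[ok] <= e99[ok]).all()

    def test_sparse_gene_flagged_undefined(self):
        vals = np.random.default_rng(1).normal(size=(2, 30))
        vals[1, 5:] = np.nan  # 5 observed < 20 required
        m = small_matrix(vals)
        e = efficacy(m, 1)
        assert np.isfinite(e.iloc[0]) and np.isnan(e.iloc[1])


class TestSelectivity:
    def test_collinear_genes_have_zero_selectivity(self):
        lo = pd.Series(np.linspace(-3, 0, 150))
        hi = 0.4 * lo + 0.2
        fit = selectivity_fit(lo, hi, min_genes=100)
        np.testing.assert_allclose(fit["selectivity"].abs().max(), 0, atol=1e-10)

    def test_double_dispersion_gives_selectivity_one(self):
        """A gene whose dispersion is twice the fitted expectation has
        S = (D - D_hat)/D_hat = 1 by the defining ratio."""
        rng = np.random.default_rng(2)
        lo = pd.Series(np.linspace(-3, -0.5, 151))
        hi = 0.4 * lo + 0.2
        dhat0 = hi.iloc[0] - lo.iloc[0]
        hi.iloc[0] = lo.iloc[0] + 2 * dhat0  # double the expected dispersion
        fit = selectivity_fit(lo, hi, min_genes=100)
        # the huber fit ignores the single outlier; its S is 1
        assert fit["selectivity"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_scale_invariance(self, default_screens):
        """Multiplying all scores by c > 0 leaves selectivity unchanged
        (the robust regression is affine-equivariant)."""
        m = default_screens["combined"]
        lo, hi = efficacy(m, 1), efficacy(m, 99)
        s1 = selectivity_fit(lo, hi)["selectivity"]
        s2 = selectivity_fit(3.0 * lo, 3.0 * hi)["selectivity"]
        pd.testing.assert_series_equal(s1, s2, atol=1e-8, rtol=1e-6)

    def test_planted_selective_rank_above_common(self, default_screens):
        m, thr, truth = (default_screens["combined"], default_screens["threshold"],
                         default_screens["truth"])
        tab = gene_score_table(m, thr)
        sel = tab.loc[truth.genes_with_label("selective"), "selectivity"]
        com = tab.loc[truth.genes_with_label("common_essential"), "selectivity"]
        assert sel.median() > com.median()

    def test_degenerate_predictor_rejected(self):
        lo = pd.Series(np.zeros(150))
        hi = pd.Series(np.ones(150))
        with pytest.raises(ValueError, match="degenerate"):
            selectivity_fit(lo, hi)


class TestOverlapIndex:
    @pytest.mark.parametrize("a,b,expected", [
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2}, {1, 2, 3, 4}, 1.0),
        ({"a", "b", "c"}, {"b", "c", "d", "e"}, 2 / 3),
    ])
    def test_values(self, a, b, expected):
        assert overlap_index(a, b) == pytest.approx(expected)

    def test_symmetric_and_nested_iff_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = set(rng.integers(0, 30, rng.integers(1, 15)).tolist())
            b = set(rng.integers(0, 30, rng.integers(1, 15)).tolist())
            assert overlap_index(a, b) == overlap_index(b, a)
            nested = a <= b or b <= a
            assert (overlap_index(a, b) == 1.0) == nested

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_index(set(), {1})


class TestPC1MixingRatio:
    def test_identical_screens_give_half(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(50, 40))
        c = small_matrix(x, Source.CRISPR)
        r = small_matrix(x, Source.SHRNA)
        assert pc1_mixing_ratio(c, r) == pytest.approx(0.5)

    def test_doubled_screen_gives_two_thirds(self):
        """S_C = 2 S_R exactly: the rank-1 covariance eigenvector is
        (2, 1)/sqrt(5), so the ratio is 2/3."""
        rng = np.random.default_rng(5)
        r = rng.normal(size=(50, 40))
        c = small_matrix(2 * r, Source.CRISPR)
        assert pc1_mixing_ratio(c, small_matrix(r, Source.SHRNA)) == \
            pytest.approx(2 / 3)

    def test_in_unit_interval_for_positive_covariance(self, default_screens):
        ca, sa = default_screens["aligned"]
        assert 0.0 <= pc1_mixing_ratio(ca, sa) <= 1.0

    def test_degenerate_rejected(self):
        z = small_matrix(np.zeros((5, 30)), Source.CRISPR)
        z2 = small_matrix(np.zeros((5, 30)), Source.SHRNA)
        with pytest.raises(ValueError, match="degenerate"):
            pc1_mixing_ratio(z, z2)


class TestInconsistency:
    def build(self, n_genes=50, n_lines=40, hot=0):
        """Background genes with 2 area-A lines each; gene `hot` with 20."""
        ce = np.zeros((n_genes, n_lines), bool)
        re_ = np.zeros((n_genes, n_lines), bool)
        ce[:, :2] = True           # every gene has 2 CRISPR-only lines
        ce[hot, :20] = True
        idx = [f"g{i}" for i in range(n_genes)]
        cols = [f"l{j}" for j in range(n_lines)]
        return (pd.DataFrame(ce, index=idx, columns=cols),
                pd.DataFrame(re_, index=idx, columns=cols))

    def test_background_rate_gene_not_flagged(self):
        ce, re_ = self.build()
        res = crispr_shrna_inconsistency(ce, re_, alpha=1e-3)
        assert res["p_a"].drop("g0").min() > 0.5
        assert not res["flag_a"].drop("g0").any()

    def test_enriched_gene_matches_hypergeometric_oracle(self):
        ce, re_ = self.build()
        res = crispr_shrna_inconsistency(ce, re_, alpha=1e-3)
        n_lines, n_genes = 40, 50
        a = 20                       # hot gene in-area conditions
        big_a = 2 * (n_genes - 1) + 20
        total = n_genes * n_lines
        oracle = hypergeom_tail_oracle(a, n_lines - a,
                                       big_a - a, total - n_lines - (big_a - a))
        assert res.loc["g0", "p_a"] == pytest.approx(oracle, rel=1e-10)
        assert res.loc["g0", "flag_a"]

    def test_zero_margin_gives_p_one(self):
        ce = pd.DataFrame(False, index=["g0", "g1"], columns=["l0", "l1"])
        res = crispr_shrna_inconsistency(ce, ce.copy())
        assert (res[["p_a", "p_b"]] == 1.0).all().all()

    def test_method_bias_genes_detected_on_synthetic(self, default_screens):
        from depmix import essential_conditions, fit_threshold
        ca, sa = default_screens["aligned"]
        truth = default_screens["truth"]
        tc, tr = fit_threshold(ca), fit_threshold(sa)
        ce = essential_conditions(ca, tc)
        re_ = essential_conditions(sa, tr)
        valid = ca.values.notna() & sa.values.notna()
        res = crispr_shrna_inconsistency(ce, re_, alpha=1e-3, valid=valid)
        crispr_only = truth.genes_with_label("crispr_only")
        shrna_only = truth.genes_with_label("shrna_only")
        assert res.loc[crispr_only, "flag_a"].mean() >= 0.9
        assert res.loc[shrna_only, "flag_b"].mean() >= 0.8
        background = truth.genes_with_label("background")
        assert res.loc[background, ["flag_a", "flag_b"]].to_numpy().mean() < 0.01


class TestFisherOverrepresentation:
    def test_nested_set_p_shrinks_with_size(self):
        prev = 1.0
        for n in (8, 16, 32):
            universe = {f"g{i}" for i in range(2 * n)}
            hits = {f"g{i}" for i in range(n)}
            res = fisher_overrepresentation(hits, universe, {"s": set(hits)})
            p = res.loc["s", "p"]
            assert p < prev
            prev = p
        assert prev < 1e-6

    def test_disjoint_set_not_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(5)}
        gs = {"s": {f"g{i}" for i in range(90, 100)}}
        assert fisher_overrepresentation(hits, universe, gs).loc["s", "p"] == \
            pytest.approx(1.0, abs=0.5)

    def test_textbook_table(self):
        """2x2 (10,5;5,80) against the enumeration oracle."""
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(15)}           # 10 + 5
        hits = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(15, 20)}
        res = fisher_overrepresentation(hits, universe, {"s": gene_set})
        assert res.loc["s", "p"] == pytest.approx(
            hypergeom_tail_oracle(10, 5, 5, 80), rel=1e-10)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overrepresentation({"x"}, {"a", "b"}, {})
        with pytest.raises(ValueError):
            fisher_overrepresentation(set(), set(), {})

    def test_bh_adjustment_monotone(self):
        universe = {f"g{i}" for i in range(200)}
        hits = {f"g{i}" for i in range(20)}
        gene_sets = {f"s{k}": {f"g{i}" for i in range(k, k + 30)}
                     for k in range(0, 60, 10)}
        res = fisher_overrepresentation(hits, universe, gene_sets)
        assert (res["p_adj"] >= res["p"] - 1e-15).all()


class TestExhaustiveFisherKernel:
    def test_all_small_tables_match_enumeration(self):
        """fisher_upper_tail equals rational-arithmetic enumeration on
        every 2x2 table with both row margins <= 14 (the kernel behind
        both Fisher operations); max abs error < 1e-12."""
        worst = 0.0
        for r1 in range(0, 15):
            for a in range(0, r1 + 1):
                b = r1 - a
                for r2 in range(0, 15):
                    for c in range(0, r2 + 1):
                        d = r2 - c
                        if r1 + r2 == 0:
                            continue
                        p = float(fisher_upper_tail(a, r1 + r2, a + c, r1))
                        oracle = hypergeom_tail_oracle(a, b, c, d)
                        worst = max(worst, abs(p - oracle))
        assert worst < 1e-12


class TestBinomialSignificance:
    def test_edge_cases(self):
        assert essential_call_significance(10, 0, 0.3) == 1.0
        assert essential_call_significance(1, 1, 0.5) == pytest.approx(0.5)

    def test_exact_summation_oracle(self):
        """n=423, p0=0.001, k=5: term-by-term pmf accumulation."""
        n, p0, k = 423, 0.001, 5
        oracle = sum(comb(n, j) * p0 ** j * (1 - p0) ** (n - j)
                     for j in range(k, n + 1))
        assert essential_call_significance(n, k, p0) == \
            pytest.approx(oracle, rel=1e-9)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            essential_call_significance(5, 6, 0.1)
        with pytest.raises(ValueError):
            essential_call_significance(5, 2, 0.0)
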