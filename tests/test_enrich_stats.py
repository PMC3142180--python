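import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from seedpath.annotation import AnnotationSet
from seedpath.fixtures import gen_background, gen_enriched_sample
from seedpath.stats import (
    ContingencyTable,
    adjust_fdr,
    binomial_pvalue,
    build_tables,
    chisq_pvalue,
    fisher_pvalue,
    hypergeom_pvalue,
    pathfind,
)

from oracles import bh_quadratic, binom_tail_exact, hypergeom_tail_exact


def random_tables(n, seed, max_n=500):
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n:
        N = int(rng.integers(2, max_n))
        M = int(rng.integers(0, N + 1))
        nn = int(rng.integers(1, N + 1))
        lo, hi = max(0, nn + M - N), min(nn, M)
        k = int(rng.integers(lo, hi + 1))
        tables.append(ContingencyTable(k, nn, M, N))
    return tables


class TestContingencyTable:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(k=-1, n=5, M=5, N=10),
            dict(k=6, n=5, M=10, N=20),   # k > n
            dict(k=3, n=5, M=2, N=20),    # k > M
            dict(k=0, n=8, M=8, N=10),    # k < n + M - N
            dict(k=2, n=12, M=5, N=10),   # n > N
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ContingencyTable(**kwargs)


class TestBuildTables:
    def aset(self, mapping, universe=None):
        return AnnotationSet(
            {g: frozenset(s) for g, s in mapping.items()},
            universe_size=universe or len(mapping),
        )

    def background_100(self):
        mapping = {}
        for i in range(10):
            mapping[f"g{i:03d}"] = {"S"}
        for i in range(10, 100):
            mapping[f"g{i:03d}"] = {"T"}
        return self.aset(mapping)

    def test_counts_match_worked_example(self):
        bg = self.background_100()
        sample = self.aset({g: bg.mapping[g] for g in ["g000", "g001", "g002", "g050", "g051"]})
        tables = dict(build_tables(sample, bg))
        assert tables["S"] == ContingencyTable(k=3, n=5, M=10, N=100)
        assert tables["T"] == ContingencyTable(k=2, n=5, M=90, N=100)

    def test_background_only_subsystem_not_tested(self):
        bg = self.background_100()
        sample = self.aset({"g000": {"S"}})
        assert [name for name, _ in build_tables(sample, bg)] == ["S"]

    def test_foreign_sample_genes_dropped_with_warning(self):
        bg = self.background_100()
        sample = self.aset({"g000": {"S"}, "alien": {"S"}})
        with pytest.warns(UserWarning, match="dropped"):
            tables = dict(build_tables(sample, bg))
        assert tables["S"].n == 1

    def test_empty_intersection_is_an_error(self):
        bg = self.background_100()
        sample = self.aset({"alien": {"S"}})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                build_tables(sample, bg)

    def test_ledgered_fixture_matches(self):
        bg, _ = gen_background(n_genes=500, n_subsystems=10, target_size=50, seed=4)
        sample, ledger = gen_enriched_sample(bg, "SS01", sample_size=30,
                                             enrichment_fraction=0.5, seed=4)
        aset = AnnotationSet({g: bg.mapping[g] for g in sample}, len(sample))
        tables = dict(build_tables(aset, bg))
        k, n, M, N = ledger.expected_table
        assert tables["SS01"] == ContingencyTable(k, n, M, N)


class TestHypergeom:
    def test_zero_k_is_one(self):
        assert hypergeom_pvalue(ContingencyTable(0, 5, 10, 100)) == 1.0

    def test_small_table_equals_exact_fraction(self):
        p = hypergeom_pvalue(ContingencyTable(4, 5, 4, 10))
        assert p == pytest.approx(6 / 252, rel=1e-12)
        assert p == pytest.approx(float(hypergeom_tail_exact(4, 5, 4, 10)), rel=1e-12)

    def test_forced_outcome_is_one(self):
        assert hypergeom_pvalue(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0, rel=1e-12)

    def test_grid_against_brute_force(self):
        for t in random_tables(60, seed=0):
            exact = float(hypergeom_tail_exact(t.k, t.n, t.M, t.N))
            assert hypergeom_pvalue(t) == pytest.approx(exact, rel=1e-12, abs=1e-300)

    def test_non_increasing_in_k(self):
        for n, M, N in [(5, 10, 100), (20, 40, 60), (7, 7, 14)]:
            lo = max(0, n + M - N)
            ps = [hypergeom_pvalue(ContingencyTable(k, n, M, N))
                  for k in range(lo, min(n, M) + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
            assert ps[0] == pytest.approx(1.0, rel=1e-12)


class TestBinomial:
    def test_all_in_half_background(self):
        assert binomial_pvalue(ContingencyTable(5, 5, 50, 100)) == pytest.approx(0.03125, rel=1e-12)

    def test_zero_k_is_one(self):
        assert binomial_pvalue(ContingencyTable(0, 5, 10, 100)) == 1.0

    def test_example_against_brute_force(self):
        expected = sum(math.comb(5, i) * 0.1**i * 0.9 ** (5 - i) for i in range(3, 6))
        assert binomial_pvalue(ContingencyTable(3, 5, 10, 100)) == pytest.approx(expected, rel=1e-12)

    def test_grid_against_brute_force(self):
        for t in random_tables(40, seed=1, max_n=200):
            exact = float(binom_tail_exact(t.k, t.n, t.M, t.N))
            assert binomial_pvalue(t) == pytest.approx(exact, rel=1e-12, abs=1e-300)

    def test_converges_to_hypergeometric_for_large_universe(self):
        # M/N fixed at 0.1, k/n fixed; the sampling fraction n/N -> 0
        deltas = []
        for N in [100, 1000, 10000, 100000]:
            t = ContingencyTable(5, 20, N // 10, N)
            deltas.append(abs(binomial_pvalue(t) - hypergeom_pvalue(t)))
        assert all(a > b for a, b in zip(deltas, deltas[1:]))
        assert deltas[-1] < 1e-4


class TestChisq:
    def test_small_expected_flags_unreliable(self):
        # expected k-cell = n*M/N = 4*4/20 = 0.8 < 5
        _, reliable = chisq_pvalue(ContingencyTable(2, 4, 4, 20))
        assert not reliable

    def test_proportional_table_gives_statistic_zero(self):
        # k/n = M/N = 1/2 with all expected cells >= 5
        p, reliable = chisq_pvalue(ContingencyTable(10, 20, 50, 100))
        assert reliable and p == pytest.approx(1.0)

    def test_zero_margin_signalled(self):
        p, reliable = chisq_pvalue(ContingencyTable(5, 5, 5, 5))
        assert not reliable and math.isnan(p)

    def test_matches_scipy_contingency_chi2(self):
        for t in random_tables(50, seed=2):
            p, reliable = chisq_pvalue(t)
            obs = t.as_2x2()
            if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
                assert not reliable
                continue
            stat, p_sp, dof, expected = sps.chi2_contingency(obs, correction=False)
            assert p == pytest.approx(p_sp, rel=1e-10)
            assert reliable == bool((expected >= 5).all())


class TestFisher:
    def test_identity_with_hypergeometric(self):
        for t in random_tables(50, seed=3):
            assert fisher_pvalue(t) == hypergeom_pvalue(t)

    def test_against_scipy_fisher_exact(self):
        for t in random_tables(50, seed=4, max_n=80):
            expected = sps.fisher_exact(t.as_2x2(), alternative="greater")[1]
            assert fisher_pvalue(t) == pytest.approx(float(expected), rel=1e-12, abs=1e-300)

    def test_zero_k_is_one(self):
        assert fisher_pvalue(ContingencyTable(0, 6, 10, 40)) == 1.0


class TestAdjustFdr:
    def test_step_up_worked_example(self):
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.3]).tolist() == [0.3]

    def test_equal_ps_unchanged(self):
        assert adjust_fdr([0.2, 0.2, 0.2]).tolist() == pytest.approx([0.2] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    def test_bonferroni_and_by_options(self):
        ps = [0.01, 0.04]
        assert adjust_fdr(ps, method="bonferroni").tolist() == pytest.approx([0.02, 0.08])
        by = adjust_fdr(ps, method="BY")
        assert (by >= adjust_fdr(ps)).all()

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_quadratic_oracle(self, ps):
        got = adjust_fdr(ps)
        expected = bh_quadratic(ps)
        assert np.allclose(got, expected, rtol=1e-12, atol=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30))
    def test_monotone_bounded_and_sandwiched_by_raw_bounds(self, ps):
        q = adjust_fdr(ps)
        assert (q <= 1.0).all()
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-12).all()
        m = len(ps)
        for i, p in enumerate(ps):
            # step-up q never drops below the raw p and never exceeds the
            # per-element bound m*p/rank (rank = last position among ties)
            rank = sum(x <= p for x in ps)
            assert p - 1e-12 <= q[i] <= min(1.0, m * p / rank) + 1e-12


class TestPathfind:
    def planted(self, seed=0):
        bg, _ = gen_background(seed=seed)
        sample, _ = gen_enriched_sample(bg, "SS01", seed=seed)
        aset = AnnotationSet({g: bg.mapping[g] for g in sample}, len(sample))
        return aset, bg

    def test_planted_subsystem_ranks_first_and_significant(self):
        sample, bg = self.planted(seed=12)
        results = pathfind(sample, bg, method="hyper")
        assert results[0].subsystem == "SS01"
        assert results[0].significant and results[0].qvalue <= 0.05

    def test_chisq_falls_back_to_fisher_on_small_tables(self):
        sample, bg = self.planted(seed=13)
        results = pathfind(sample, bg, method="chisq")
        small = [r for r in results
                 if (np.outer(r.table.as_2x2().sum(1), r.table.as_2x2().sum(0))
                     / r.table.N < 5).any()]
        assert small and all(r.method_used == "fisher" for r in small)

    def test_gene_order_permutation_invariant(self):
        bg, _ = gen_background(n_genes=300, n_subsystems=8, target_size=30, seed=6)
        genes = sorted(bg.mapping)[:25]
        fwd = AnnotationSet({g: bg.mapping[g] for g in genes}, 25)
        rev = AnnotationSet({g: bg.mapping[g] for g in reversed(genes)}, 25)
        assert pathfind(fwd, bg) == pathfind(rev, bg)

    def test_sorted_by_q_then_p_then_name(self):
        sample, bg = self.planted(seed=14)
        results = pathfind(sample, bg)
        keys = [(r.qvalue, r.pvalue, r.subsystem) for r in results]
        assert keys == sorted(keys)

    def test_fdr_m_covers_all_tested_subsystems(self):
        sample, bg = self.planted(seed=15)
        results = pathfind(sample, bg)
        ps = [r.pvalue for r in sorted(results, key=lambda r: r.subsystem)]
        qs = [r.qvalue for r in sorted(results, key=lambda r: r.subsystem)]
        assert np.allclose(qs, bh_quadratic(ps), rtol=1e-12)

    def test_unknown_method_rejected(self):
        sample, bg = self.planted(seed=16)
        with pytest.raises(ValueError):
            pathfind(sample, bg, method="anova")
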