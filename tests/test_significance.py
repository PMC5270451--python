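"""Empirical q-values, combined calls, overlap/robustness evaluators."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from mobas.association import GenotypeDataset
from mobas.io import SnpRecord
from mobas.scoring import Subnetwork
from mobas.significance import (
    chi_square_2x2,
    combine_significance,
    empirical_qvalues,
    hypergeometric_overlap,
    rank_overlap,
    run_null,
    subsample_dataset,
)

from conftest import make_instance


def naive_qvalues(observed, nulls):
    """Counting oracle: literally pool the top-i scores of each null run."""
    out = []
    for i, s in enumerate(observed, start=1):
        pooled = []
        for lst in nulls:
            pooled.extend(sorted(lst, reverse=True)[:i])
        out.append(sum(1 for x in pooled if x >= s) / len(pooled))
    return out


class TestEmpiricalQvalues:
    def test_rank_one_counts_null_tops(self):
        assert empirical_qvalues([10.0], [[4.0], [12.0]]) == [0.5]

    def test_score_above_all_nulls_gives_zero(self):
        assert empirical_qvalues([100.0], [[4.0, 2.0], [3.0]])[0] == 0.0

    def test_rank_two_pools_top_two_of_each(self):
        qs = empirical_qvalues([10.0, 5.0], [[9.0, 6.0], [3.0, 1.0]])
        assert qs[1] == pytest.approx(0.5)  # pooled {9,6,3,1}, two >= 5

    def test_short_null_lists_pool_what_exists(self):
        qs = empirical_qvalues([5.0, 4.0, 3.0], [[6.0], [2.0, 1.0]])
        assert qs == naive_qvalues([5.0, 4.0, 3.0], [[6.0], [2.0, 1.0]])

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            empirical_qvalues([], [[1.0]])
        with pytest.raises(ValueError):
            empirical_qvalues([1.0], [])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        observed=st.lists(st.floats(-5, 5), min_size=1, max_size=8).map(
            lambda xs: sorted(xs, reverse=True)
        ),
        nulls=st.lists(
            st.lists(st.floats(-5, 5), min_size=0, max_size=8),
            min_size=1,
            max_size=5,
        ).filter(lambda ls: any(ls)),
    )
    def test_matches_naive_counting_oracle(self, observed, nulls):
        assert empirical_qvalues(observed, nulls) == naive_qvalues(observed, nulls)

    def test_q_non_decreasing_as_score_decreases(self):
        nulls = [[5.0, 3.0, 1.0], [4.0, 2.0, 0.5]]
        qs = [empirical_qvalues([s], nulls)[0] for s in (6.0, 4.5, 2.5, 0.0)]
        assert qs == sorted(qs)


class TestCombineSignificance:
    def test_significant_top_module(self):
        # q_pheno=0.04, q_net below resolution -> combined 0.04, significant
        res = combine_significance(0.04, 0.009)
        assert res.q_combined == 0.04 and res.significant

    def test_insignificant_node_based_module(self):
        res = combine_significance(0.37, 0.45)
        assert res.q_combined == 0.45 and not res.significant

    def test_double_zero(self):
        res = combine_significance(0.0, 0.0)
        assert res.q_combined == 0.0 and res.significant

    def test_threshold_is_strict(self):
        assert not combine_significance(0.05, 0.01).significant

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_significance(-0.1, 0.5)


class TestHypergeometricOverlap:
    def _enumerate_p(self, n_universe, n_a, n_b, min_overlap):
        """Exhaustive enumeration over all draws of B from the universe."""
        total = math.comb(n_universe, n_b)
        favorable = sum(
            math.comb(n_a, k) * math.comb(n_universe - n_a, n_b - k)
            for k in range(min_overlap, min(n_a, n_b) + 1)
        )
        return favorable / total

    def test_worked_example(self):
        universe = [f"g{i}" for i in range(10)]
        a, b = universe[:4], universe[:5]  # overlap 4
        p = hypergeometric_overlap(a, b, universe)
        assert p == pytest.approx(6 / 252)

    def test_disjoint_sets_give_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        assert hypergeometric_overlap(universe[:3], universe[5:8], universe) == 1.0

    def test_bonferroni_cap(self):
        universe = [f"g{i}" for i in range(10)]
        p = hypergeometric_overlap(universe[:4], universe[:5], universe, n_tests=50)
        assert p == 1.0

    def test_sets_must_be_in_universe(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(["x"], ["g0"], ["g0", "g1"])

    @pytest.mark.parametrize(
        "n_universe,n_a,n_b,overlap",
        [(8, 3, 4, 2), (12, 5, 6, 3), (10, 2, 9, 2), (7, 7, 3, 3)],
    )
    def test_matches_exhaustive_enumeration(self, n_universe, n_a, n_b, overlap):
        universe = [f"g{i}" for i in range(n_universe)]
        a = universe[:n_a]
        b = universe[n_a - overlap : n_a - overlap + n_b]
        p = hypergeometric_overlap(a, b, universe)
        assert p == pytest.approx(self._enumerate_p(n_universe, n_a, n_b, overlap), rel=1e-12)


class TestChiSquare2x2:
    def test_independent_table(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_closed_form_example(self):
        stat, p = chi_square_2x2([[20, 10], [10, 20]])
        assert stat == pytest.approx(60 * (400 - 100) ** 2 / 30**4)
        assert p == pytest.approx(0.00982, abs=5e-5)

    def test_perfect_association(self):
        stat, p = chi_square_2x2([[0, 5], [5, 0]])
        assert stat == pytest.approx(10.0)
        assert p == pytest.approx(0.00157, abs=5e-5)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])

    @pytest.mark.parametrize(
        "table", [[[12, 3], [7, 9]], [[1, 50], [30, 2]], [[5, 5], [5, 6]]]
    )
    def test_agrees_with_scipy_without_correction(self, table):
        stat, p = chi_square_2x2(table)
        expected = chi2_contingency(np.asarray(table), correction=False)
        assert stat == pytest.approx(expected.statistic, rel=1e-12)
        assert p == pytest.approx(expected.pvalue, rel=1e-12)


class TestSubsampling:
    def _dataset(self, n_cases=100, n_controls=60):
        n = n_cases + n_controls
        rng = np.random.default_rng(0)
        return GenotypeDataset(
            samples=[f"s{i}" for i in range(n)],
            phenotype=np.array([1] * n_cases + [0] * n_controls, dtype=np.int8),
            genotypes=rng.integers(0, 3, size=(5, n)).astype(np.int8),
            snps=[SnpRecord(snp_id=f"rs{i}") for i in range(5)],
        )

    def test_group_proportions_preserved(self):
        sub = subsample_dataset(self._dataset(), 0.5, seed=1)
        assert sub.n_cases == 50 and sub.n_controls == 30

    def test_keep_all_is_identity(self):
        ds = self._dataset()
        sub = subsample_dataset(ds, 1.0, seed=1)
        assert sub.samples == ds.samples
        assert np.array_equal(sub.genotypes, ds.genotypes)

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.2])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            subsample_dataset(self._dataset(), fraction)

    def test_emptied_group_rejected(self):
        with pytest.raises(ValueError):
            subsample_dataset(self._dataset(n_cases=100, n_controls=2), 0.1)

    def test_reproducible(self):
        a = subsample_dataset(self._dataset(), 0.5, seed=9)
        b = subsample_dataset(self._dataset(), 0.5, seed=9)
        assert a.samples == b.samples


def _mods(sets, ranks=None):
    return [
        Subnetwork(nodes=tuple(s), score=float(10 - i), scheme="mobas",
                   rank=(ranks[i] if ranks else i + 1))
        for i, s in enumerate(sets)
    ]


class TestRankOverlap:
    def test_identical_lists_map_to_identity(self):
        mods = _mods([{"a", "b"}, {"c"}, {"d", "e"}])
        mapping = rank_overlap(mods, mods)
        assert {k: v.best_rank for k, v in mapping.items()} == {1: 1, 2: 2, 3: 3}

    def test_disjoint_reference_flagged_with_zero_overlap(self):
        ref = _mods([{"x", "y"}])
        test = _mods([{"a"}, {"b"}])
        (match,) = rank_overlap(ref, test).values()
        assert match.overlap == 0 and match.best_rank == 1

    def test_hand_built_example_matches_brute_force(self):
        ref = _mods([{"a", "b", "c"}, {"d", "e"}, {"f"}])
        test = _mods([{"c", "d", "e"}, {"a", "b"}, {"f", "g"}])
        mapping = rank_overlap(ref, test)
        # brute force: ref1 overlaps test1 by 1, test2 by 2 -> rank 2
        assert mapping[1].best_rank == 2 and mapping[1].overlap == 2
        assert mapping[2].best_rank == 1 and mapping[2].overlap == 2
        assert mapping[3].best_rank == 3 and mapping[3].overlap == 1

    def test_tie_prefers_larger_jaccard(self):
        ref = _mods([{"a", "b"}])
        test = _mods([{"a", "z", "w"}, {"b"}])  # both overlap 1
        (match,) = rank_overlap(ref, test).values()
        assert match.best_rank == 2  # jaccard 1/2 beats 1/4

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            rank_overlap([], _mods([{"a"}]))


class TestRunNull:
    def test_cardinality_and_determinism(self, rng):
        ctx = make_instance(rng, n_nodes=12, p_edge=0.3, scheme="mobas")
        kwargs = dict(
            network=ctx.network, m=3, seed=7, scores=ctx.scores,
            background=ctx.background, scheme="mobas",
        )
        lists_a = run_null("net", **kwargs)
        lists_b = run_null("net", **kwargs)
        assert len(lists_a) == 3
        assert lists_a == lists_b

    def test_zero_swaps_reproduces_observed_scores(self, rng):
        from mobas.search import find_all_modules

        ctx = make_instance(rng, n_nodes=12, p_edge=0.4, scheme="mobas")
        observed = [m.score for m in find_all_modules(ctx.network, ctx)]
        lists = run_null(
            "net", network=ctx.network, m=2, seed=0, scores=ctx.scores,
            background=ctx.background, scheme="mobas", swaps_per_edge=0,
        )
        for lst in lists:
            assert lst == pytest.approx(observed)

    def test_invalid_m_rejected(self, rng):
        ctx = make_instance(rng, scheme="mobas")
        with pytest.raises(ValueError):
            run_null("net", network=ctx.network, m=0, scores=ctx.scores,
                     background=ctx.background)

    def test_pheno_model_needs_inputs(self, rng):
        ctx = make_instance(rng, scheme="mobas")
        with pytest.raises(ValueError, match="dataset"):
            run_null("pheno", network=ctx.network, m=2, background=ctx.background)
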