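"""The 2x2 overlap statistics: table building, Fisher test, permutations."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epioverlap import (
    ContingencyTable,
    GeneList,
    InfeasibleError,
    InputError,
    build_table,
    compare_lists,
    fisher_overlap,
    hypergeometric_moments,
    permutation_overlap,
)


def make_lists(size_a, size_b, overlap, prefix="g"):
    a = GeneList("A", [f"{prefix}{i}" for i in range(size_a)])
    b = GeneList("B", [f"{prefix}{i}" for i in range(size_a - overlap,
                                                     size_a - overlap + size_b)])
    return a, b


def hypergeom_pmf(k, n_total, n_a, n_b):
    if not (max(0, n_a + n_b - n_total) <= k <= min(n_a, n_b)):
        return 0.0
    return comb(n_a, k) * comb(n_total - n_a, n_b - k) / comb(n_total, n_b)


def brute_force_fisher(a, b, c, d):
    """Enumerate the conditional (hypergeometric) distribution of the a-cell."""
    n_total, n_row, n_col = a + b + c + d, a + b, a + c
    support = range(max(0, n_row + n_col - n_total), min(n_row, n_col) + 1)
    pmf = {k: hypergeom_pmf(k, n_total, n_row, n_col) for k in support}
    p_greater = sum(p for k, p in pmf.items() if k >= a)
    cutoff = pmf[a] * (1 + 1e-9)
    p_two = sum(p for p in pmf.values() if p <= cutoff)
    return min(p_greater, 1.0), min(p_two, 1.0)


class TestBuildTable:
    def test_study_scale_cells(self):
        a, b = make_lists(1181, 589, 45)
        t = build_table(a, b, 23_382)
        assert t.as_tuple() == (45, 1136, 544, 21_657)

    def test_disjoint_lists(self):
        a, b = make_lists(2, 3, 0)
        assert build_table(a, b, 10).as_tuple() == (0, 2, 3, 5)

    def test_identical_lists(self):
        a = GeneList("A", ["w", "x", "y", "z"])
        b = GeneList("B", ["w", "x", "y", "z"])
        assert build_table(a, b, 10).as_tuple() == (4, 0, 0, 6)

    def test_background_smaller_than_union_is_infeasible(self):
        a, b = make_lists(5, 5, 0)
        with pytest.raises(InfeasibleError):
            build_table(a, b, 9)

    def test_negative_cell_rejected(self):
        with pytest.raises(InputError):
            ContingencyTable(1, -1, 0, 5)


class TestFisherOverlap:
    @pytest.mark.parametrize("table, expected_or", [
        ((0, 2, 3, 5), 0.0),
        ((5, 5, 5, 85), 17.0),
        ((1, 0, 0, 1), math.inf),
    ])
    def test_sample_odds_ratio_cases(self, table, expected_or):
        assert fisher_overlap(ContingencyTable(*table)).odds_ratio_sample \
            == expected_or

    def test_all_zero_table_rejected(self):
        with pytest.raises(InputError):
            fisher_overlap(ContingencyTable(0, 0, 0, 0))

    def test_cmle_differs_from_sample_or(self):
        f = fisher_overlap(ContingencyTable(45, 1136, 544, 21_657))
        assert f.odds_ratio_sample == pytest.approx(1.577, abs=5e-4)
        assert f.odds_ratio_cmle == pytest.approx(f.odds_ratio_sample, rel=0.05)
        assert f.odds_ratio_cmle != f.odds_ratio_sample

    @settings(derandomize=True, max_examples=60)
    @given(a=st.integers(0, 12), b=st.integers(0, 12),
           c=st.integers(0, 12), d=st.integers(0, 12))
    def test_p_values_match_enumeration_oracle(self, a, b, c, d):
        """Exact tail enumeration over the hypergeometric support, N <= 48."""
        if a + b + c + d == 0:
            return
        f = fisher_overlap(ContingencyTable(a, b, c, d))
        p_greater, p_two = brute_force_fisher(a, b, c, d)
        assert f.p_greater == pytest.approx(p_greater, rel=1e-9, abs=1e-12)
        assert f.p_two_sided == pytest.approx(p_two, rel=1e-7, abs=1e-12)


class TestHypergeometricMoments:
    def test_simple_mean(self):
        mean, sd = hypergeometric_moments(20, 20, 100)
        assert mean == pytest.approx(4.0)
        assert sd > 0

    def test_empty_list_has_zero_moments(self):
        assert hypergeometric_moments(10, 0, 100) == (0.0, 0.0)

    def test_moments_match_exact_pmf_enumeration(self):
        n_total, n_a, n_b = 60, 25, 18
        pmf = [hypergeom_pmf(k, n_total, n_a, n_b) for k in range(n_b + 1)]
        mean = sum(k * p for k, p in enumerate(pmf))
        var = sum(k * k * p for k, p in enumerate(pmf)) - mean**2
        got_mean, got_sd = hypergeometric_moments(n_a, n_b, n_total)
        assert got_mean == pytest.approx(mean)
        assert got_sd == pytest.approx(math.sqrt(var))

    def test_tiny_background_rejected(self):
        with pytest.raises(InputError):
            hypergeometric_moments(1, 1, 1)


class TestPermutationOverlap:
    def test_mean_near_hypergeometric_mean(self):
        res = permutation_overlap(20, 20, 100, observed=4, n_perm=10_000, seed=7)
        mean, sd = hypergeometric_moments(20, 20, 100)
        assert abs(res.mean - mean) < 3 * sd / math.sqrt(10_000)

    def test_degenerate_list_covers_background(self):
        res = permutation_overlap(50, 20, 50, observed=20, n_perm=200, seed=0)
        assert res.mean == 20.0 and res.sd == 0.0
        assert math.isnan(res.z)
        assert res.p == 0.0  # nothing can exceed the full overlap

    def test_same_seed_bit_identical(self):
        r1 = permutation_overlap(30, 40, 200, 10, n_perm=500, seed=11)
        r2 = permutation_overlap(30, 40, 200, 10, n_perm=500, seed=11)
        assert r1 == r2

    def test_subset_and_count_methods_agree_distributionally(self):
        args = dict(size_a=40, size_b=50, background_size=300, observed=7,
                    n_perm=8_000)
        r_sub = permutation_overlap(**args, seed=3, method="subsets")
        r_cnt = permutation_overlap(**args, seed=4, method="counts")
        mean, sd = hypergeometric_moments(40, 50, 300)
        se = sd / math.sqrt(8_000)
        for r in (r_sub, r_cnt):
            assert abs(r.mean - mean) < 4 * se
            assert abs(r.sd - sd) < 4 * sd / math.sqrt(2 * 7_999)

    def test_smoothed_p_never_zero(self):
        r = permutation_overlap(10, 10, 40, observed=10, n_perm=50, seed=0,
                                smoothed=True)
        assert r.p == pytest.approx(1 / 51)

    def test_single_permutation_p_is_zero_or_one(self):
        r = permutation_overlap(10, 10, 40, observed=0, n_perm=1, seed=0)
        assert r.p in (0.0, 1.0)

    def test_oversized_list_rejected(self):
        with pytest.raises(InputError):
            permutation_overlap(11, 5, 10, observed=0)


class TestCompareLists:
    def test_symmetric_in_a_and_b(self):
        a, b = make_lists(30, 20, 5)
        r1 = compare_lists(a, b, 100, n_perm=0)
        r2 = compare_lists(b, a, 100, n_perm=0)
        assert r1.table.a == r2.table.a
        assert r1.odds_ratio_sample == r2.odds_ratio_sample
        assert r1.fisher_p_greater == pytest.approx(r2.fisher_p_greater,
                                                    rel=1e-12)
        assert r1.fisher_p_two_sided == pytest.approx(r2.fisher_p_two_sided,
                                                      rel=1e-12)

    def test_identical_singletons_give_infinite_or(self):
        a = GeneList("A", ["g"])
        b = GeneList("B", ["g"])
        r = compare_lists(a, b, 2, n_perm=0)
        assert r.table.a == 1
        assert r.odds_ratio_sample == math.inf

    def test_empty_list_rejected(self):
        with pytest.raises(InputError):
            compare_lists(GeneList("A", ["g"]), GeneList("B", []), 10)

    def test_result_serialization_roundtrip(self):
        import json
        a, b = make_lists(30, 20, 5)
        r = compare_lists(a, b, 100, n_perm=200, seed=1)
        d = json.loads(r.to_json())
        assert d["overlap_count"] == 5
        assert d["table"] == {"a": 5, "b": 25, "c": 15, "d": 55}
        assert len(d["overlap_genes"]) == 5
        assert d["n_perm"] == 200
        row = r.to_tsv_row().split("\t")
        assert len(row) == len(r.TSV_HEADER.split("\t"))

    def test_permutation_p_close_to_exact_tail_on_small_instances(self):
        """The empirical permutation p estimates the exact strictly-greater
        hypergeometric tail; they agree within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        for _ in range(4):
            n_total = int(rng.integers(40, 120))
            size_a = int(rng.integers(5, n_total // 2))
            size_b = int(rng.integers(5, n_total // 2))
            overlap = int(rng.integers(0, min(size_a, size_b) // 2 + 1))
            a, b = make_lists(size_a, size_b, overlap)
            r = compare_lists(a, b, n_total, n_perm=10_000,
                              seed=int(rng.integers(1000)))
            p_strict = sum(
                hypergeom_pmf(k, n_total, size_a, size_b)
                for k in range(overlap + 1, min(size_a, size_b) + 1)
            )
            band = 4 * math.sqrt(max(p_strict * (1 - p_strict), 1e-6) / 10_000)
            assert abs(r.perm_p - p_strict) <= band + 1e-9
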