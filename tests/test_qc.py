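import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinnet.genotypes import GenotypeTable, MISSING
from kinnet.qc import (
    allele_frequencies,
    expected_heterozygosity,
    filter_loci,
    find_duplicate_genotypes,
    hwe_exact_test,
    ld_test,
    locus_summary,
    null_allele_check,
    observed_heterozygosity,
    sequential_bonferroni,
)

from .conftest import draw_genotypes


def one_locus_table(pairs):
    return GenotypeTable(
        [f"i{k}" for k in range(len(pairs))],
        ["L"],
        np.asarray(pairs).reshape(len(pairs), 1, 2),
    )


class TestAlleleFrequencies:
    def test_hand_counts(self):
        t = one_locus_table([[1, 1], [1, 2], [2, 2]])
        f = allele_frequencies(t)["L"]
        assert f == {1: 0.5, 2: 0.5}

    def test_single_individuals(self):
        assert allele_frequencies(one_locus_table([[5, 5]]))["L"] == {5: 1.0}
        assert allele_frequencies(one_locus_table([[1, 2]]))["L"] == {1: 0.5, 2: 0.5}

    def test_missing_excluded_and_sum_to_one(self):
        t = one_locus_table([[1, 3], [MISSING, MISSING], [3, 3]])
        f = allele_frequencies(t)
        assert f.n_gene_copies["L"] == 4
        assert abs(sum(f["L"].values()) - 1.0) < 1e-12

    def test_all_missing_locus_warns_and_drops(self):
        t = one_locus_table([[MISSING, MISSING]])
        with pytest.warns(UserWarning, match="no typed"):
            f = allele_frequencies(t)
        assert "L" not in f.freqs


class TestHeterozygosity:
    def test_hand_values(self):
        calls = np.array([[1, 1], [1, 2], [2, 2]])
        assert observed_heterozygosity(calls) == pytest.approx(1 / 3)
        # raw 1 - sum p^2 = 0.5; unbiased (6/5) * 0.5 = 0.6
        assert expected_heterozygosity(calls) == pytest.approx(0.6)

    def test_all_heterozygous(self):
        calls = np.tile([1, 2], (10, 1))
        assert observed_heterozygosity(calls) == 1.0

    def test_many_equifrequent_alleles_approach_1_minus_1_over_k(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(1, 16, size=(4000, 2))
        he = expected_heterozygosity(calls)
        assert he == pytest.approx(14 / 15, abs=0.01)

    def test_monomorphic(self):
        calls = np.tile([4, 4], (5, 1))
        summary = locus_summary(one_locus_table(calls.reshape(5, 1, 2)))[0]
        assert summary.He == 0.0 and summary.Fis is None and summary.hwe_p == 1.0


class TestHWEExactTest:
    def test_monomorphic_is_one(self):
        assert hwe_exact_test(np.tile([2, 2], (5, 1))) == 1.0

    def test_enumeration_matches_monte_carlo(self):
        rng = np.random.default_rng(1)
        for trial in range(4):
            calls = rng.choice([1, 2, 3], size=(10, 2), p=[0.5, 0.3, 0.2])
            p_enum = hwe_exact_test(calls)
            p_mc = hwe_exact_test(calls, n_mc=200_000, seed=trial,
                                  max_enum_tables=1)
            assert p_mc == pytest.approx(p_enum, abs=0.01)

    def test_extreme_heterozygote_excess(self):
        calls = np.tile([1, 2], (100, 1))
        p = hwe_exact_test(calls, n_mc=20_000, seed=0, max_enum_tables=1)
        assert p < 0.001


class TestNullAlleles:
    def test_zero_when_ho_equals_he(self):
        rng = np.random.default_rng(2)
        calls = draw_genotypes(rng, 200, 1, 8)[:, 0, :]
        res = null_allele_check(calls, seed=0)
        ho = observed_heterozygosity(calls)
        he = expected_heterozygosity(calls)
        assert res.chakraborty == pytest.approx((he - ho) / (he + ho))
        assert res.brookfield1 == pytest.approx((he - ho) / (1 + he))

    def test_estimator_arithmetic(self):
        # Ho = 0.365, He = 0.871 give Chakraborty ~0.409, Brookfield-1 ~0.270
        ho, he = 0.365, 0.871
        assert (he - ho) / (he + ho) == pytest.approx(0.409, abs=0.001)
        assert (he - ho) / (1 + he) == pytest.approx(0.270, abs=0.001)

    def test_monomorphic_undefined(self):
        res = null_allele_check(np.tile([3, 3], (6, 1)))
        assert res.chakraborty is None and not res.excess_flag

    def test_brookfield_recovers_simulated_null_frequency(self):
        # null allele at frequency 0.2 among 9 visible equifrequent alleles;
        # null heterozygotes look homozygous, null/null looks missing
        rng = np.random.default_rng(3)
        q, k, n = 0.2, 9, 500
        p = np.full(k + 1, (1 - q) / k)
        p[k] = q  # index k = null
        raw = rng.choice(k + 1, size=(n, 2), p=p)
        calls = np.sort(raw, axis=1) + 1
        is_null = raw == k
        obs = calls.copy()
        both = is_null.all(axis=1)
        one = is_null.any(axis=1) & ~both
        vis = np.where(is_null[one, 0], calls[one, 1], calls[one, 0])
        obs[one, 0] = obs[one, 1] = vis
        obs[both] = MISSING
        res = null_allele_check(obs[~both], seed=1)
        assert res.brookfield1 == pytest.approx(q, abs=0.05)
        assert res.excess_flag


class TestLDTest:
    def test_duplicated_locus_detected(self):
        rng = np.random.default_rng(4)
        a = draw_genotypes(rng, 20, 1, 5)
        calls = np.concatenate([a, a], axis=1)
        t = GenotypeTable([f"i{k}" for k in range(20)], ["A", "B"], calls)
        assert ld_test(t, "A", "B", n_perm=2000, seed=0) <= 0.01

    def test_monomorphic_locus_gives_one(self):
        rng = np.random.default_rng(5)
        a = draw_genotypes(rng, 10, 1, 5)
        b = np.tile([[2, 2]], (10, 1)).reshape(10, 1, 2)
        t = GenotypeTable(
            [f"i{k}" for k in range(10)], ["A", "B"],
            np.concatenate([a, b], axis=1),
        )
        assert ld_test(t, "A", "B", seed=0, n_perm=100) == 1.0


class TestSequentialBonferroni:
    def test_hand_holm(self):
        res = sequential_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        assert np.allclose(res.adjusted, [0.03, 0.06, 0.06])
        assert list(res.reject) == [True, False, False]

    def test_single_and_degenerate(self):
        assert sequential_bonferroni([0.04]).reject[0]
        assert not sequential_bonferroni([1.0, 1.0]).reject.any()

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            sequential_bonferroni([0.5, 1.2])
        with pytest.raises(ValueError):
            sequential_bonferroni([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_holm_rejects_superset_of_bonferroni(self, ps):
        alpha = 0.05
        res = sequential_bonferroni(ps, alpha)
        bonf = np.asarray(ps) * len(ps) < alpha
        assert np.all(res.reject[bonf])
        # adjusted p monotone non-decreasing in sorted order
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(res.adjusted[order]) >= -1e-12)


class TestDuplicatesAndFiltering:
    def test_planted_duplicate_found(self):
        rng = np.random.default_rng(6)
        calls = draw_genotypes(rng, 5, 8, 6)
        calls[4] = calls[0]
        t = GenotypeTable([f"i{k}" for k in range(5)], [f"L{j}" for j in range(8)], calls)
        matches, _ = find_duplicate_genotypes(t)
        assert [(m[0], m[1]) for m in matches] == [("i0", "i4")]

    def test_unrelated_panel_has_no_duplicates(self):
        rng = np.random.default_rng(7)
        calls = draw_genotypes(rng, 85, 14, 5)
        t = GenotypeTable([f"i{k}" for k in range(85)], [f"L{j}" for j in range(14)], calls)
        matches, incomparable = find_duplicate_genotypes(t)
        assert matches == [] and incomparable == []

    def test_no_shared_loci_reported_incomparable(self):
        calls = np.array(
            [[[1, 2], [MISSING, MISSING]], [[MISSING, MISSING], [3, 4]]]
        )
        t = GenotypeTable(["a", "b"], ["A", "B"], calls)
        matches, incomparable = find_duplicate_genotypes(t, min_shared_loci=1)
        assert matches == [] and incomparable == [("a", "b")]

    def test_filter_loci(self):
        rng = np.random.default_rng(8)
        loci = [f"Na{j:02d}" for j in range(1, 15)] + ["LS15", "Cli107"]
        t = GenotypeTable(
            [f"i{k}" for k in range(4)], loci, draw_genotypes(rng, 4, 16, 4)
        )
        kept = filter_loci(t, ["LS15", "Cli107"])
        assert kept.n_loci == 14 and "LS15" not in kept.loci
        assert filter_loci(t, []) == t
        with pytest.raises(ValueError, match="unknown"):
            filter_loci(t, ["nope"])
        with pytest.warns(UserWarning, match="all loci"):
            empty = filter_loci(t, loci)
        assert empty.n_loci == 0
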