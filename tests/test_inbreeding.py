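import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kinnet.genotypes import GenotypeTable, IndividualMeta, MISSING
from kinnet.inbreeding import (
    internal_relatedness,
    ir_covariate_summary,
    ir_locus_subset,
    ir_random_mating_null,
    ir_vector,
)
from kinnet.qc import AlleleFrequencyTable, allele_frequencies

from .conftest import draw_genotypes, equifreq_table, mendel_child


class TestInternalRelatedness:
    def test_single_heterozygous_locus_is_minus_one(self):
        f = AlleleFrequencyTable({"L": {1: 0.5, 2: 0.5}}, {"L": 10})
        assert internal_relatedness(np.array([[1, 2]]), f, ["L"]) == -1.0

    def test_fully_homozygous_is_one_regardless_of_freqs(self):
        f = AlleleFrequencyTable(
            {"A": {1: 0.9, 2: 0.1}, "B": {1: 0.2, 2: 0.8}}, {"A": 10, "B": 10}
        )
        assert internal_relatedness(np.array([[1, 1], [2, 2]]), f, ["A", "B"]) == 1.0

    def test_hand_value_zero(self):
        f = AlleleFrequencyTable(
            {"A": {1: 0.5, 2: 0.5}, "B": {3: 0.5, 4: 0.5}}, {"A": 10, "B": 10}
        )
        ir = internal_relatedness(np.array([[1, 1], [3, 4]]), f, ["A", "B"])
        assert ir == pytest.approx(0.0)

    def test_monomorphic_and_missing_loci_excluded(self):
        f = AlleleFrequencyTable(
            {"A": {1: 0.5, 2: 0.5}, "M": {7: 1.0}}, {"A": 10, "M": 10}
        )
        ir = internal_relatedness(
            np.array([[1, 2], [7, 7]]), f, ["A", "M"]
        )
        assert ir == -1.0  # only locus A used
        with pytest.raises(ValueError, match="undefined"):
            internal_relatedness(np.array([[MISSING, MISSING], [7, 7]]), f, ["A", "M"])

    @settings(max_examples=60, deadline=None)
    @given(
        genos=st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4)),
                       min_size=1, max_size=10),
        seed=st.integers(0, 100),
    )
    def test_bounded_and_one_iff_fully_homozygous(self, genos, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet([1.5] * 4)
        p = np.maximum(p, 0.05)
        p /= p.sum()
        fmap = {a + 1: float(p[a]) for a in range(4)}
        loci = [f"L{j}" for j in range(len(genos))]
        f = AlleleFrequencyTable({l: fmap for l in loci}, {l: 100 for l in loci})
        calls = np.sort(np.array(genos).reshape(-1, 2), axis=1).reshape(-1, 2)
        ir = internal_relatedness(calls, f, loci)
        assert -1.0 - 1e-9 <= ir <= 1.0 + 1e-9
        if all(a == b for a, b in calls):
            assert ir == pytest.approx(1.0)
        else:
            assert ir < 1.0

    def test_expectation_tracks_inbreeding_coefficient(self):
        """Mean IR of simulated offspring approximates pedigree F at
        equifrequent loci (outbred F=0 and full-sib-mating F=0.25)."""
        rng = np.random.default_rng(0)
        L, K, n = 20, 10, 4000
        freqs = equifreq_table(L, K)
        loci = list(freqs.freqs)
        # F = 0
        irs0 = []
        for _ in range(n // 2):
            pa, ma = draw_genotypes(rng, 2, L, K)
            irs0.append(internal_relatedness(mendel_child(rng, pa, ma), freqs, loci))
        assert np.mean(irs0) == pytest.approx(0.0, abs=0.02)
        # F = 0.25 (parents are full sibs)
        irs = []
        for _ in range(n // 2):
            gpa, gma = draw_genotypes(rng, 2, L, K)
            s1 = mendel_child(rng, gpa, gma)
            s2 = mendel_child(rng, gpa, gma)
            irs.append(internal_relatedness(mendel_child(rng, s1, s2), freqs, loci))
        assert np.mean(irs) == pytest.approx(0.25, abs=0.02)


class TestRandomMatingNull:
    @staticmethod
    def _population(rng, n_m=6, n_f=8, n_off=20, L=10, K=6):
        males = draw_genotypes(rng, n_m, L, K)
        females = draw_genotypes(rng, n_f, L, K)
        offs = [
            mendel_child(rng, males[rng.integers(n_m)], females[rng.integers(n_f)])
            for _ in range(n_off)
        ]
        ids = [f"m{i}" for i in range(n_m)] + [f"f{i}" for i in range(n_f)] + \
            [f"o{i}" for i in range(n_off)]
        calls = np.concatenate([males, females, np.array(offs)])
        t = GenotypeTable(ids, [f"L{j}" for j in range(L)], calls)
        return t, ids[:n_m], ids[n_m:n_m + n_f], ids[n_m + n_f:]

    def test_single_iteration_degenerate_p(self):
        rng = np.random.default_rng(1)
        t, males, females, offs = self._population(rng)
        freqs = allele_frequencies(t, males + females)
        obs = ir_vector(t, freqs, offs)
        res = ir_random_mating_null(t, males, females, obs, freqs,
                                    n_iter=1, seed=0)
        assert res.p in (0.5, 1.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        t, males, females, offs = self._population(rng)
        freqs = allele_frequencies(t, males + females)
        obs = ir_vector(t, freqs, offs)
        a = ir_random_mating_null(t, males, females, obs, freqs, n_iter=50, seed=9)
        b = ir_random_mating_null(t, males, females, obs, freqs, n_iter=50, seed=9)
        assert np.array_equal(a.null_means, b.null_means) and a.p == b.p

    def test_inbred_offspring_detected(self):
        """Offspring of full-sib matings score high against a random-mating
        null of the unrelated adult pool in most replicate datasets."""
        rng = np.random.default_rng(3)
        L, K, n_off = 14, 10, 52
        rejections = 0
        reps = 20
        for _ in range(reps):
            males = draw_genotypes(rng, 10, L, K)
            females = draw_genotypes(rng, 12, L, K)
            offs = []
            for _ in range(n_off):
                pa = males[rng.integers(10)]
                ma = females[rng.integers(12)]
                s1, s2 = mendel_child(rng, pa, ma), mendel_child(rng, pa, ma)
                offs.append(mendel_child(rng, s1, s2))  # F = 0.25
            ids = [f"m{i}" for i in range(10)] + [f"f{i}" for i in range(12)] + \
                [f"o{i}" for i in range(n_off)]
            t = GenotypeTable(ids, [f"L{j}" for j in range(L)],
                              np.concatenate([males, females, np.array(offs)]))
            freqs = allele_frequencies(t, ids[:22])
            obs = ir_vector(t, freqs, ids[22:])
            res = ir_random_mating_null(t, ids[:10], ids[10:22], obs, freqs,
                                        n_iter=200, seed=int(rng.integers(2**31)))
            rejections += res.p <= 0.05
        assert rejections / reps >= 0.8

    def test_requires_both_sexes(self):
        rng = np.random.default_rng(4)
        t, males, females, offs = self._population(rng)
        with pytest.raises(ValueError):
            ir_random_mating_null(t, [], females, [0.0], n_iter=5)


class TestLocusSubset:
    def test_identity_when_all_loci_pass(self):
        rng = np.random.default_rng(5)
        calls = draw_genotypes(rng, 10, 6, 8)
        t = GenotypeTable([f"i{k}" for k in range(10)],
                          [f"L{j}" for j in range(6)], calls)
        freqs = equifreq_table(6, 8)
        full = ir_vector(t, freqs)
        sub, kept = ir_locus_subset(t, freqs, min_alleles=5)
        assert kept == t.loci
        assert np.allclose(full, sub)

    def test_threshold_two_keeps_all_polymorphic(self):
        rng = np.random.default_rng(6)
        calls = draw_genotypes(rng, 10, 4, 3)
        t = GenotypeTable([f"i{k}" for k in range(10)],
                          [f"L{j}" for j in range(4)], calls)
        _, kept = ir_locus_subset(t, allele_frequencies(t), min_alleles=2)
        assert set(kept) == set(t.loci)

    def test_no_passing_locus_errors(self):
        rng = np.random.default_rng(7)
        calls = draw_genotypes(rng, 10, 3, 2)
        t = GenotypeTable([f"i{k}" for k in range(10)],
                          [f"L{j}" for j in range(3)], calls)
        with pytest.raises(ValueError, match="no locus"):
            ir_locus_subset(t, allele_frequencies(t), min_alleles=8)


class TestCovariateSummary:
    @staticmethod
    def _meta(lengths):
        return {
            i: IndividualMeta(id=i, sex="unknown", total_length_cm=l,
                              stage=None, cohort_year=2006 + (k % 2))
            for k, (i, l) in enumerate(lengths.items())
        }

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(8)
        lengths = {f"i{k}": float(rng.uniform(60, 310)) for k in range(85)}
        ir = {i: -0.0005 * l + 0.078 + rng.normal(0, 0.05)
              for i, l in lengths.items()}
        cov = ir_covariate_summary(pd.Series(ir), self._meta(lengths))
        se = 0.05 / (np.std(list(lengths.values())) * np.sqrt(85))
        assert cov.slope == pytest.approx(-0.0005, abs=3 * se)

    def test_constant_ir_gives_zero_slope(self):
        lengths = {f"i{k}": 100.0 + k for k in range(5)}
        cov = ir_covariate_summary(
            pd.Series({i: 0.1 for i in lengths}), self._meta(lengths)
        )
        assert cov.slope == pytest.approx(0.0)

    def test_constant_covariate_undefined(self):
        lengths = {f"i{k}": 100.0 for k in range(5)}
        cov = ir_covariate_summary(
            pd.Series({i: 0.1 * k for k, i in enumerate(lengths)}),
            self._meta(lengths),
        )
        assert cov.slope is None
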