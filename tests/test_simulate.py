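import filecmp

import numpy as np
import pytest
from scipy.stats import chisquare

from kinnet.genotypes import MISSING
from kinnet.simulate import (
    NULL_ALLELE,
    PedigreeSpec,
    apply_observation_model,
    make_study_fixture,
    pedigree_kinship,
    pedigree_relatedness,
    simulate_founders,
    simulate_pedigree,
)


def small_spec(**kw):
    defaults = dict(
        n_founder_males=8, n_founder_females=10, n_breeding_years=4,
        n_loci=8, alleles_per_locus=tuple([6] * 8), error_rate=0.0,
        missing_rate=0.0, seed=0,
    )
    defaults.update(kw)
    return PedigreeSpec(**defaults)


class TestFounders:
    def test_equifrequent_heterozygosity(self):
        spec = small_spec(n_founder_males=1000, n_founder_females=1000,
                          alleles_per_locus=tuple([10] * 8),
                          freq_profile="equifrequent")
        rng = np.random.default_rng(1)
        founders, freqs, sex = simulate_founders(spec, rng)
        het = np.mean(founders.calls[:, :, 0] != founders.calls[:, :, 1])
        assert het == pytest.approx(0.9, abs=0.01)

    def test_biallelic_heterozygosity(self):
        spec = small_spec(n_founder_males=2000, n_founder_females=2000,
                          alleles_per_locus=tuple([2] * 8),
                          freq_profile="equifrequent")
        founders, _, _ = simulate_founders(spec, np.random.default_rng(2))
        het = np.mean(founders.calls[:, :, 0] != founders.calls[:, :, 1])
        assert het == pytest.approx(0.5, abs=0.01)

    def test_seeded_determinism(self):
        spec = small_spec()
        a, fa, _ = simulate_founders(spec, np.random.default_rng(7))
        b, fb, _ = simulate_founders(spec, np.random.default_rng(7))
        assert a == b and fa.freqs == fb.freqs


class TestPedigree:
    @staticmethod
    def run(spec, seed=3):
        rng = np.random.default_rng(seed)
        founders, freqs, sex = simulate_founders(spec, rng)
        return simulate_pedigree(spec, founders, freqs, sex, rng)

    def test_gene_dropping_conserves_alleles(self):
        truth = self.run(small_spec())
        geno = truth.genotypes_true
        idx = {i: k for k, i in enumerate(geno.individuals)}
        for _, row in truth.pedigree.iterrows():
            child = geno.calls[idx[row["id"]]]
            mom = geno.calls[idx[row["mother"]]]
            dad = geno.calls[idx[row["father"]]]
            for l in range(geno.n_loci):
                a, b = child[l]
                parental = set(mom[l]) | set(dad[l])
                assert a in parental and b in parental

    def test_mendelian_ratios_one_two_one(self):
        # offspring of {1,2} x {1,2} should be 1:2:1 for 11/12/22
        rng = np.random.default_rng(4)
        mother = np.array([[1, 2]])
        father = np.array([[1, 2]])
        counts = {11: 0, 12: 0, 22: 0}
        for _ in range(12000):
            a = mother[0, rng.integers(2)]
            b = father[0, rng.integers(2)]
            counts[min(a, b) * 10 + max(a, b)] += 1
        stat, p = chisquare(
            [counts[11], counts[12], counts[22]], [3000, 6000, 3000]
        )
        assert p > 0.001

    def test_strict_biennial_cycle(self):
        truth = self.run(small_spec(female_cycle="biennial", breeding_prob=1.0))
        litters = truth.pedigree.groupby("mother")["cohort_year"].unique()
        for years in litters:
            years = sorted(years)
            assert all(b - a >= 2 for a, b in zip(years, years[1:]))

    def test_monandry_by_construction(self):
        spec = small_spec(sires_per_litter_probs={1: 1.0})
        truth = self.run(spec)
        sires = truth.pedigree.groupby(["mother", "cohort_year"])["father"].nunique()
        assert (sires == 1).all()

    def test_full_polyandry_of_multi_young_litters(self):
        spec = small_spec(sires_per_litter_probs={2: 0.6, 3: 0.4})
        truth = self.run(spec)
        grouped = truth.pedigree.groupby(["mother", "cohort_year"])
        for _, lit in grouped:
            if len(lit) >= 2:
                assert lit["father"].nunique() >= 2


class TestObservationModel:
    def test_identity_when_error_free(self):
        spec = small_spec(adult_sampling_fraction=1.0)
        rng = np.random.default_rng(5)
        founders, freqs, sex = simulate_founders(spec, rng)
        truth = simulate_pedigree(spec, founders, freqs, sex, rng)
        observed, meta = apply_observation_model(truth, spec, rng)
        sub = truth.genotypes_true.subset_individuals(truth.sampled)
        assert observed == sub
        assert set(meta) == set(truth.sampled)

    def test_total_error_destroys_parentage_signal(self):
        spec = small_spec(error_rate=1.0, adult_sampling_fraction=1.0)
        rng = np.random.default_rng(6)
        founders, freqs, sex = simulate_founders(spec, rng)
        truth = simulate_pedigree(spec, founders, freqs, sex, rng)
        observed, _ = apply_observation_model(truth, spec, rng)
        idx = {i: k for k, i in enumerate(observed.individuals)}
        mism = 0
        checked = 0
        for _, row in truth.pedigree.iterrows():
            if row["id"] not in idx or row["mother"] not in idx:
                continue
            child = observed.calls[idx[row["id"]]]
            mom = observed.calls[idx[row["mother"]]]
            shared = (
                (child[:, 0:1] == mom[:, 0:1]) | (child[:, 0:1] == mom[:, 1:2])
                | (child[:, 1:2] == mom[:, 0:1]) | (child[:, 1:2] == mom[:, 1:2])
            ).any(axis=1)
            mism += np.sum(~shared)
            checked += len(shared)
        assert checked > 0 and mism / checked > 0.2

    def test_null_alleles_masked_to_homozygotes_or_missing(self):
        spec = small_spec(null_allele_freqs={"Na01": 0.4},
                          adult_sampling_fraction=1.0)
        rng = np.random.default_rng(7)
        founders, freqs, sex = simulate_founders(spec, rng)
        assert NULL_ALLELE in freqs["Na01"]
        truth = simulate_pedigree(spec, founders, freqs, sex, rng)
        observed, _ = apply_observation_model(truth, spec, rng)
        col = observed.calls[:, 0, :]
        assert not np.any(col == NULL_ALLELE)
        # with q=0.4 some null/null homozygotes must exist -> missing calls
        assert np.any(col == MISSING)


class TestPedigreeKinship:
    def test_classical_relationships(self):
        parents = {
            "c1": ("m", "f"), "c2": ("m", "f"),  # full sibs
            "h1": ("m", "f2"),                   # half sib of c1
            "g1": ("c1", "x"),                   # grandchild of m
        }
        phi = pedigree_kinship(parents)
        assert 2 * phi("c1", "c2") == pytest.approx(0.5)
        assert 2 * phi("c1", "m") == pytest.approx(0.5)
        assert 2 * phi("c1", "h1") == pytest.approx(0.25)
        assert 2 * phi("g1", "m") == pytest.approx(0.25)
        assert 2 * phi("g1", "c2") == pytest.approx(0.25)  # avuncular
        assert phi("m", "f") == 0.0


class TestStudyFixture:
    def test_shape_and_truth(self):
        fx = make_study_fixture(seed=99)
        adults = [i for i, m in fx.meta.items() if m.stage == "mature"]
        juveniles = [i for i, m in fx.meta.items() if m.stage != "mature"]
        assert fx.table.n_individuals == 85
        assert len(adults) == 33 and len(juveniles) == 52
        sexes = [fx.meta[i].sex for i in adults]
        assert sexes.count("M") == 13 and sexes.count("F") == 20
        assert fx.table.n_loci == 16 and fx.null_loci == ["LS15", "Cli107"]
        ped = fx.truth.pedigree
        juv_ped = ped[ped["cohort_year"].notna()]
        assert len(juv_ped) == 52
        mothers = set(juv_ped["mother"])
        fathers = set(juv_ped["father"])
        assert len(mothers) == 21 and len(fathers) == 20
        assert len(mothers | fathers) == 41
        litters = juv_ped.groupby(["mother", "cohort_year"])
        assert litters.ngroups == 29
        multi = [lit for _, lit in litters if len(lit) >= 2]
        poly = [lit for lit in multi if lit["father"].nunique() >= 2]
        assert len(multi) == 9 and len(poly) == 7
        assert len(set(juv_ped["nursery"])) == 4

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_study_fixture(seed=5, out_dir=d1)
        make_study_fixture(seed=5, out_dir=d2)
        for name in ("genotypes.gen", "metadata.csv", "truth.json"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False)

    def test_truth_relatedness_matrix(self):
        fx = make_study_fixture(seed=99)
        r = pedigree_relatedness(fx.truth, [fx.outgroup, "M01", "M02"])
        assert r.loc[fx.outgroup, "M01"] == 0.0
        assert r.loc["M01", "M02"] in (0.0, 0.25, 0.5)
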