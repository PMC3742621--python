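import numpy as np
import pytest

from kinnet.genotypes import GenotypeTable, MISSING
from kinnet.parentage import (
    BreederCount,
    ParentageAssignment,
    ParentageScorer,
    SibshipSolution,
    assign_parents,
    count_breeders,
    delta_criticals,
    exhaustive_sibship,
    litter_table,
    mendelian_mismatches,
    parent_lod,
    reconstruct_parent_genotypes,
    sibship_reconstruct,
)
from kinnet.genotypes import IndividualMeta
from kinnet.qc import AlleleFrequencyTable

from .conftest import draw_genotypes, equifreq_table, mendel_child


class TestMendelianMismatches:
    def test_true_parent_has_none(self):
        rng = np.random.default_rng(0)
        pa = draw_genotypes(rng, 1, 14, 10)[0]
        ma = draw_genotypes(rng, 1, 14, 10)[0]
        child = mendel_child(rng, pa, ma)
        assert mendelian_mismatches(child, pa) == 0

    def test_opposite_homozygotes(self):
        assert mendelian_mismatches(np.array([[1, 1]]), np.array([[2, 2]])) == 1

    def test_missing_loci_excluded(self):
        off = np.array([[1, 1], [MISSING, MISSING]])
        cand = np.array([[2, 2], [1, 1]])
        assert mendelian_mismatches(off, cand) == 1
        with pytest.raises(ValueError):
            mendelian_mismatches(
                np.array([[MISSING, MISSING]]), np.array([[1, 1]])
            )

    def test_unrelated_candidates_usually_mismatch(self):
        rng = np.random.default_rng(1)
        pa = draw_genotypes(rng, 1, 14, 10)[0]
        ma = draw_genotypes(rng, 1, 14, 10)[0]
        child = mendel_child(rng, pa, ma)
        counts = [
            mendelian_mismatches(child, draw_genotypes(rng, 1, 14, 10)[0])
            for _ in range(300)
        ]
        assert np.median(counts) >= 3


class TestParentLOD:
    def test_uninformative_locus_is_zero(self):
        f = AlleleFrequencyTable({"X": {1: 0.5, 2: 0.5}}, {"X": 100})
        assert parent_lod(np.array([[1, 2]]), np.array([[1, 1]]), f, 0.0) == \
            pytest.approx(0.0)

    def test_exclusion_at_zero_error(self):
        f = AlleleFrequencyTable({"X": {1: 0.5, 2: 0.5}}, {"X": 100})
        assert parent_lod(np.array([[1, 1]]), np.array([[2, 2]]), f, 0.0) == -np.inf

    def test_additive_over_loci(self):
        rng = np.random.default_rng(2)
        freqs = equifreq_table(2, 6)
        f0 = AlleleFrequencyTable({"L0": freqs["L0"]}, {"L0": 100})
        f1 = AlleleFrequencyTable({"L1": freqs["L1"]}, {"L1": 100})
        off = draw_genotypes(rng, 1, 2, 6)[0]
        cand = draw_genotypes(rng, 1, 2, 6)[0]
        total = parent_lod(off, cand, freqs, 0.01)
        parts = parent_lod(off[:1], cand[:1], f0, 0.01) + \
            parent_lod(off[1:], cand[1:], f1, 0.01)
        assert total == pytest.approx(parts)

    def test_true_parents_outrank_unrelated(self):
        rng = np.random.default_rng(3)
        freqs = equifreq_table(14, 10)
        wins = 0
        for _ in range(100):
            pa, ma = draw_genotypes(rng, 2, 14, 10)
            child = mendel_child(rng, pa, ma, 10, error_rate=0.01)
            lod_true = parent_lod(child, pa, freqs, 0.01)
            lod_rand = max(
                parent_lod(child, draw_genotypes(rng, 1, 14, 10)[0], freqs, 0.01)
                for _ in range(5)
            )
            wins += lod_true > lod_rand
        assert wins >= 99


class TestDeltaCriticals:
    def test_all_sampled_informative_loci_give_zero(self):
        freqs = equifreq_table(14, 10)
        crit = delta_criticals(freqs, 20, 1.0, n_sim=4000, seed=0)
        assert crit == 0.0

    def test_monotone_in_confidence(self):
        freqs = equifreq_table(6, 4)  # weak panel so thresholds bind
        lo = delta_criticals(freqs, 20, 0.5, confidence=0.80, n_sim=6000, seed=1)
        hi = delta_criticals(freqs, 20, 0.5, confidence=0.99, n_sim=6000, seed=1)
        assert hi >= lo >= 0.0

    def test_invalid_proportion(self):
        with pytest.raises(ValueError):
            delta_criticals(equifreq_table(2, 4), 5, 0.0)


def _assignment_setup(rng, n_off, n_mothers, n_fathers, sampled=True):
    L, K = 14, 10
    mothers = draw_genotypes(rng, n_mothers, L, K)
    fathers = draw_genotypes(rng, n_fathers, L, K)
    offs, truth = [], []
    for i in range(n_off):
        mi = rng.integers(n_mothers)
        fi = rng.integers(n_fathers)
        if sampled:
            offs.append(mendel_child(rng, mothers[mi], fathers[fi], K, 0.01))
        else:
            offs.append(
                mendel_child(rng, draw_genotypes(rng, 1, L, K)[0],
                             draw_genotypes(rng, 1, L, K)[0], K, 0.01)
            )
        truth.append((f"m{mi}", f"f{fi}"))
    ids = [f"m{i}" for i in range(n_mothers)] + \
        [f"f{i}" for i in range(n_fathers)] + [f"o{i}" for i in range(n_off)]
    calls = np.concatenate([mothers, fathers, np.array(offs)])
    table = GenotypeTable(ids, [f"L{j}" for j in range(L)], calls)
    return table, truth


class TestAssignParents:
    def test_trio_recovered(self):
        rng = np.random.default_rng(4)
        table, truth = _assignment_setup(rng, 10, 5, 5)
        scorer = ParentageScorer(table, equifreq_table(14, 10), 0.01)
        asg = assign_parents(
            scorer, [f"o{i}" for i in range(10)],
            [f"m{i}" for i in range(5)], [f"f{i}" for i in range(5)],
            {"mother": 0.0, "father": 0.0},
        )
        for a, (tm, tf) in zip(asg, truth):
            assert a.outcome == "pair"
            assert (a.mother_ref, a.father_ref) == (tm, tf)

    def test_empty_candidate_set_leaves_unassigned(self):
        rng = np.random.default_rng(5)
        table, _ = _assignment_setup(rng, 3, 2, 2)
        scorer = ParentageScorer(table, equifreq_table(14, 10), 0.01)
        asg = assign_parents(scorer, ["o0", "o1", "o2"], [],
                             ["f0", "f1"], {"mother": 0.0, "father": 0.0})
        assert all(a.confidence_mother == "unassigned" for a in asg)


class TestSibship:
    def test_two_full_sibs_form_one_family(self):
        rng = np.random.default_rng(6)
        pa, ma = draw_genotypes(rng, 2, 14, 10)
        calls = np.array([mendel_child(rng, pa, ma) for _ in range(2)])
        t = GenotypeTable(["o0", "o1"], [f"L{j}" for j in range(14)], calls)
        scorer = ParentageScorer(t, equifreq_table(14, 10), 0.01)
        res = sibship_reconstruct(scorer, ["o0", "o1"], n_replicates=2, seed=0,
                                  min_steps=1500)
        assert list(res.best.maternal_families.values()) == [["o0", "o1"]]
        assert list(res.best.paternal_families.values()) == [["o0", "o1"]]

    def test_single_offspring_no_candidates(self):
        rng = np.random.default_rng(7)
        calls = draw_genotypes(rng, 1, 6, 5)
        t = GenotypeTable(["o0"], [f"L{j}" for j in range(6)], calls)
        scorer = ParentageScorer(t, equifreq_table(6, 5), 0.01)
        res = sibship_reconstruct(scorer, ["o0"], n_replicates=1, seed=0,
                                  min_steps=200)
        assert res.best.maternal_families == {"#1": ["o0"]}
        assert res.best.paternal_families == {"*1": ["o0"]}

    def test_known_parent_must_be_a_candidate(self):
        rng = np.random.default_rng(8)
        calls = draw_genotypes(rng, 2, 6, 5)
        t = GenotypeTable(["o0", "o1"], [f"L{j}" for j in range(6)], calls)
        scorer = ParentageScorer(t, equifreq_table(6, 5), 0.01)
        bad = [ParentageAssignment("o0", mother_ref="ghost",
                                   confidence_mother="strict95")]
        with pytest.raises(ValueError, match="candidate mothers"):
            sibship_reconstruct(scorer, ["o0", "o1"], known_assignments=bad)

    def test_annealer_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        pa1, ma1, pa2, ma2 = draw_genotypes(rng, 4, 14, 10)
        calls = np.array(
            [mendel_child(rng, pa1, ma1, 10, 0.01) for _ in range(3)]
            + [mendel_child(rng, pa2, ma2, 10, 0.01) for _ in range(2)]
        )
        ids = [f"o{i}" for i in range(5)]
        t = GenotypeTable(ids, [f"L{j}" for j in range(14)], calls)
        scorer = ParentageScorer(t, equifreq_table(14, 10), 0.01)
        score_ex, sol_ex = exhaustive_sibship(scorer, ids)
        res = sibship_reconstruct(scorer, ids, n_replicates=2, seed=1,
                                  min_steps=4000)
        assert res.best.loglik >= score_ex - 1e-6


class TestReconstructParentGenotypes:
    def test_known_coparent_forces_missing_allele(self):
        # four offspring all {1,2}; known mother {1,1} -> father carries 2
        loci = ["L0"]
        calls = np.array([[[1, 1]]] + [[[1, 2]]] * 4)
        ids = ["mom", "o0", "o1", "o2", "o3"]
        t = GenotypeTable(ids, loci, calls)
        freqs = AlleleFrequencyTable({"L0": {1: 0.4, 2: 0.3, 3: 0.3}}, {"L0": 100})
        scorer = ParentageScorer(t, freqs, 0.01)
        sol = SibshipSolution(
            offspring=["o0", "o1", "o2", "o3"],
            maternal_families={"mom": ["o0", "o1", "o2", "o3"]},
            paternal_families={"*1": ["o0", "o1", "o2", "o3"]},
            loglik=0.0,
        )
        recon = reconstruct_parent_genotypes(sol, scorer)
        for geno in recon["*1"]["L0"]:
            assert 2 in geno

    def test_single_offspring_ambiguity_contains_truth(self):
        rng = np.random.default_rng(10)
        pa, ma = draw_genotypes(rng, 2, 1, 10)
        child = mendel_child(rng, pa, ma)
        t = GenotypeTable(["o0"], ["L0"], child[None, :, :])
        scorer = ParentageScorer(t, equifreq_table(1, 10), 0.01)
        sol = SibshipSolution(
            offspring=["o0"],
            maternal_families={"#1": ["o0"]},
            paternal_families={"*1": ["o0"]},
            loglik=0.0,
        )
        recon = reconstruct_parent_genotypes(sol, scorer, tie_tol=1e-6)
        options = recon["#1"]["L0"]
        # a compatible parent shares at least one allele with the child
        assert any(set(g) & set(int(a) for a in child[0]) for g in options)

    def test_large_error_free_families_recover_truth(self):
        rng = np.random.default_rng(11)
        hits = 0
        trials = 40
        for _ in range(trials):
            pa, ma = draw_genotypes(rng, 2, 1, 10)
            kids = np.array([mendel_child(rng, pa, ma) for _ in range(6)])
            ids = [f"o{i}" for i in range(6)]
            t = GenotypeTable(ids, ["L0"], kids)
            scorer = ParentageScorer(t, equifreq_table(1, 10), 0.01)
            sol = SibshipSolution(
                offspring=ids,
                maternal_families={"#1": ids},
                paternal_families={"*1": ids},
                loglik=0.0,
            )
            recon = reconstruct_parent_genotypes(sol, scorer, tie_tol=1e-6)
            truth = {tuple(sorted(pa[0])), tuple(sorted(ma[0]))}
            got = set(map(tuple, recon["#1"]["L0"])) | set(
                map(tuple, recon["*1"]["L0"])
            )
            hits += bool(truth & got)
        assert hits / trials >= 0.9


class TestCountsAndLitters:
    def test_breeder_count_arithmetic(self):
        bc = BreederCount(4, 8, 17, 12)
        assert bc.total == 41

    def test_empty_solution_counts_zero(self):
        sol = SibshipSolution([], {}, {}, 0.0)
        bc = count_breeders(sol)
        assert bc.total == 0

    @staticmethod
    def _meta(offspring, years, sites=None):
        return {
            o: IndividualMeta(
                id=o, sex="unknown", total_length_cm=70.0, stage="juvenile",
                site=(sites or {}).get(o, "A"), cohort_year=years.get(o),
            )
            for o in offspring
        }

    def test_polyandry_fraction_seven_of_nine(self):
        # 9 multi-young litters, 7 with >=2 sires, plus singletons
        mat, pat, meta_years = {}, {}, {}
        off_counter = 0
        for lit in range(9):
            kids = [f"k{off_counter + j}" for j in range(2)]
            off_counter += 2
            mat[f"#m{lit}"] = kids
            n_sires = 2 if lit < 7 else 1
            for j, k in enumerate(kids):
                pat.setdefault(f"*s{lit}_{j % n_sires}", []).append(k)
            for k in kids:
                meta_years[k] = 2006
        sol = SibshipSolution(
            offspring=sum(mat.values(), []),
            maternal_families=mat, paternal_families=pat, loglik=0.0,
        )
        lt = litter_table(sol, self._meta(sol.offspring, meta_years))
        assert lt.n_multi_young == 9 and lt.n_polyandrous == 7
        assert lt.polyandry_fraction == pytest.approx(7 / 9)

    def test_all_singletons_polyandry_undefined(self):
        mat = {"#1": ["a"], "#2": ["b"]}
        pat = {"*1": ["a"], "*2": ["b"]}
        sol = SibshipSolution(["a", "b"], mat, pat, 0.0)
        lt = litter_table(sol, self._meta(["a", "b"], {"a": 2006, "b": 2007}))
        assert lt.polyandry_fraction is None

    def test_unknown_year_listed_separately(self):
        mat = {"#1": ["a", "b"]}
        pat = {"*1": ["a", "b"]}
        sol = SibshipSolution(["a", "b"], mat, pat, 0.0)
        lt = litter_table(sol, self._meta(["a", "b"], {"a": 2006}))
        assert len(lt.litters) == 1 and len(lt.unknown_year) == 1
        # breeder total equals distinct parent refs in the litter table
        refs = {l.mother_ref for l in lt.litters + lt.unknown_year}
        refs |= set().union(*(l.sires for l in lt.litters + lt.unknown_year))
        assert count_breeders(sol).total == len(refs)
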