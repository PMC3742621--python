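"""Shared fixtures: simulation helpers and the study-shaped pipeline run."""

from dataclasses import dataclass

import numpy as np
import pytest

from kinnet.genotypes import GenotypeTable
from kinnet.parentage import (
    ParentageScorer,
    assign_parents,
    count_breeders,
    delta_criticals,
    sibship_reconstruct,
)
from kinnet.qc import AlleleFrequencyTable, allele_frequencies, filter_loci, qc_report
from kinnet.relatedness import PairScorer, relatedness_matrix, significance_filter
from kinnet.simulate import make_study_fixture


def equifreq_table(n_loci: int, n_alleles: int) -> AlleleFrequencyTable:
    loci = [f"L{j}" for j in range(n_loci)]
    return AlleleFrequencyTable(
        {l: {a: 1.0 / n_alleles for a in range(1, n_alleles + 1)} for l in loci},
        {l: 10_000 for l in loci},
    )


def draw_genotypes(rng, n, n_loci, n_alleles):
    """HWE draws at equifrequent loci; (n, n_loci, 2) canonical calls."""
    return np.sort(rng.integers(1, n_alleles + 1, size=(n, n_loci, 2)), axis=2)


def mendel_child(rng, mother, father, n_alleles=None, error_rate=0.0):
    """One offspring from two (L, 2) parents, optional per-locus error."""
    L = mother.shape[0]
    a = mother[np.arange(L), rng.integers(0, 2, L)]
    b = father[np.arange(L), rng.integers(0, 2, L)]
    g = np.sort(np.stack([a, b], axis=1), axis=1)
    if error_rate > 0:
        err = rng.random(L) < error_rate
        if err.any():
            g[err] = np.sort(
                rng.integers(1, n_alleles + 1, size=(int(err.sum()), 2)), axis=1
            )
    return g


def oracle_pair_likelihood(g1, g2, freqs: dict, k) -> float:
    """Exhaustive enumeration over explicit allele draws per IBD state."""
    alleles = list(freqs)
    g1, g2 = tuple(sorted(g1)), tuple(sorted(g2))

    def ms(x, y):
        return (x, y) if x <= y else (y, x)

    def phwe(g):
        return sum(
            freqs[x] * freqs[y]
            for x in alleles
            for y in alleles
            if ms(x, y) == g
        )

    q0 = phwe(g1) * phwe(g2)
    q1 = sum(
        freqs[s] * freqs[u] * freqs[v]
        for s in alleles
        for u in alleles
        for v in alleles
        if ms(s, u) == g1 and ms(s, v) == g2
    )
    q2 = phwe(g1) if g1 == g2 else 0.0
    k0, k1, k2 = k
    return k0 * q0 + k1 * q1 + k2 * q2


@dataclass
class StudyPipeline:
    fixture: object
    qc_summaries: list
    retained: GenotypeTable
    adults: list
    juveniles: list
    relatedness: object
    dyads: object  # with significance columns
    scorer: PairScorer
    assignments: list
    sibship: object
    breeders: object
    truth_parents: dict


@pytest.fixture(scope="session")
def study_pipeline() -> StudyPipeline:
    """The full study-shaped analysis on the deterministic fixture.

    QC -> locus filtering -> adult relatedness with significance screening
    -> parentage assignment -> sibship reconstruction -> breeder counting.
    """
    fx = make_study_fixture(seed=2013)
    summaries = qc_report(fx.table, alpha=0.05, seed=7, n_mc=20_000)
    flagged = [s.locus for s in summaries if "null_allele_suspect" in s.flags]
    retained = filter_loci(fx.table, flagged)
    adults = sorted(i for i, m in fx.meta.items() if m.stage == "mature")
    juveniles = sorted(i for i, m in fx.meta.items() if m.stage != "mature")
    rel = relatedness_matrix(retained, ids=adults)
    scorer = PairScorer(retained)
    dyads = significance_filter(scorer, rel.dyads, alpha=0.05,
                                n_null=100_000, seed=11)
    females = sorted(i for i in adults if fx.meta[i].sex == "F")
    males = sorted(i for i in adults if fx.meta[i].sex == "M")
    freqs = allele_frequencies(retained)
    pscorer = ParentageScorer(retained, freqs, 0.01)
    crit_m = delta_criticals(freqs, len(females), 0.25, n_sim=10_000, seed=21)
    crit_f = delta_criticals(freqs, len(males), 0.5, n_sim=10_000, seed=22)
    assignments = assign_parents(pscorer, juveniles, females, males,
                                 {"mother": crit_m, "father": crit_f})
    sib = sibship_reconstruct(
        pscorer, juveniles, females, males, known_assignments=assignments,
        pool_mothers=33, pool_fathers=27, n_replicates=3, seed=77,
    )
    breeders = count_breeders(sib.best, assignments)
    truth_parents = {
        r["id"]: (r["mother"], r["father"])
        for _, r in fx.truth.pedigree.iterrows()
    }
    return StudyPipeline(
        fixture=fx,
        qc_summaries=summaries,
        retained=retained,
        adults=adults,
        juveniles=juveniles,
        relatedness=rel,
        dyads=dyads,
        scorer=scorer,
        assignments=assignments,
        sibship=sib,
        breeders=breeders,
        truth_parents=truth_parents,
    )
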