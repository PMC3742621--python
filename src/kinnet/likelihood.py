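"""Per-locus genotype probability and transmission tables.

Everything downstream of QC (pairwise relatedness, parentage LOD scores,
sibship likelihoods, simulated nulls) works on the same primitives: the HWE
probability of each unordered genotype, and the probability that a parent
with genotype ``g_p`` produces a child genotype ``g_c`` when the co-parent
is an independent draw from the gene pool.  This module precomputes those
as dense per-locus tables so the likelihood code elsewhere stays vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeTable
from .qc import AlleleFrequencyTable

__all__ = ["LocusModel", "build_locus_models", "encode_table", "mendel_vector"]


@dataclass
class LocusModel:
    """Dense probability tables for one locus.

    Attributes
    ----------
    alleles : (k,) allele codes, ascending
    p : (k,) allele frequencies
    genotypes : (G, 2) allele *indices* with i <= j
    gp : (G,) HWE genotype probabilities
    T1 : (G, G) ``T1[parent, child]`` = P(child | one allele transmitted
        uniformly from parent, the other drawn from the gene pool)
    gcode : (k, k) map from an unordered allele-index pair to genotype index
    """

    locus: str
    alleles: np.ndarray
    p: np.ndarray
    genotypes: np.ndarray
    gp: np.ndarray
    T1: np.ndarray
    gcode: np.ndarray

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    def i1(self) -> np.ndarray:
        """(k, G) matrix I1[s, g] = P(free gene-pool draw completes genotype g
        given one IBD allele s): p_other if s is carried by g, else 0."""
        k, G = self.n_alleles, self.n_genotypes
        out = np.zeros((k, G))
        for g, (i, j) in enumerate(self.genotypes):
            if i == j:
                out[i, g] = self.p[i]
            else:
                out[i, g] = self.p[j]
                out[j, g] = self.p[i]
        return out

    def pair_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(G, G) joint genotype-pair probabilities sharing 0/1/2 alleles IBD."""
        P0 = np.outer(self.gp, self.gp)
        i1 = self.i1()
        P1 = (i1 * self.p[:, None]).T @ i1
        P2 = np.diag(self.gp)
        return P0, P1, P2


def _build_one(locus: str, freq_map: dict[int, float]) -> LocusModel:
    alleles = np.array(sorted(freq_map), dtype=np.int64)
    p = np.array([freq_map[int(a)] for a in alleles], dtype=float)
    k = len(alleles)
    genotypes = np.array(
        [(i, j) for i in range(k) for j in range(i, k)], dtype=np.int64
    )
    G = len(genotypes)
    gp = np.empty(G)
    gcode = np.full((k, k), -1, dtype=np.int64)
    for g, (i, j) in enumerate(genotypes):
        gp[g] = p[i] ** 2 if i == j else 2.0 * p[i] * p[j]
        gcode[i, j] = gcode[j, i] = g
    # T1[parent, child]: transmitted allele uniform over parent's two slots,
    # the other child allele an independent gene-pool draw.
    T1 = np.zeros((G, G))
    for gpar, (a, b) in enumerate(genotypes):
        for trans, w in ((a, 0.5), (b, 0.5)):
            for gch, (c, d) in enumerate(genotypes):
                if c == d:
                    if trans == c:
                        T1[gpar, gch] += w * p[c]
                else:
                    if trans == c:
                        T1[gpar, gch] += w * p[d]
                    elif trans == d:
                        T1[gpar, gch] += w * p[c]
    return LocusModel(locus, alleles, p, genotypes, gp, T1, gcode)


def build_locus_models(freqs: AlleleFrequencyTable) -> dict[str, LocusModel]:
    """One :class:`LocusModel` per locus in the frequency table."""
    return {locus: _build_one(locus, freqs[locus]) for locus in freqs.loci()}


def encode_table(
    table: GenotypeTable, models: dict[str, LocusModel]
) -> np.ndarray:
    """Encode calls as genotype indices per (individual, locus); -1 = missing.

    Raises if an observed allele is absent from the frequency table: the
    frequencies must be estimated on a superset of the scored individuals.
    """
    loci = [l for l in table.loci if l in models]
    codes = np.full((table.n_individuals, len(loci)), -1, dtype=np.int64)
    for out_l, locus in enumerate(loci):
        model = models[locus]
        lookup = {int(a): i for i, a in enumerate(model.alleles)}
        calls = table.locus_calls(locus)
        for i in range(table.n_individuals):
            a, b = calls[i]
            if a == MISSING:
                continue
            try:
                ia, ib = lookup[int(a)], lookup[int(b)]
            except KeyError as exc:
                raise ValueError(
                    f"allele {exc.args[0]} at locus {locus} absent from the "
                    "frequency table"
                ) from None
            codes[i, out_l] = model.gcode[ia, ib]
    return codes


def mendel_vector(model: LocusModel, g_co: int, g_child: int) -> np.ndarray:
    """P(child | parent=g, co-parent=g_co) for every genotype g of one parent.

    Both parental transmissions are uniform over the parent's two allele
    slots; returns a (G,) vector over the focal parent's genotype.
    """
    G = model.n_genotypes
    out = np.zeros(G)
    ca, cb = model.genotypes[g_co]
    cc, cd = model.genotypes[g_child]
    for g in range(G):
        a, b = model.genotypes[g]
        prob = 0.0
        for x in (a, b):
            for y in (ca, cb):
                lo, hi = (x, y) if x <= y else (y, x)
                if lo == cc and hi == cd:
                    prob += 0.25
        out[g] = prob
    return out
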