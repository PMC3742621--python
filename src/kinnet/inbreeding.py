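"""Internal relatedness (IR) and the random-mating Monte Carlo null.

IR is an allele-frequency-weighted homozygosity of a single individual:

    IR = (2H - sum f_i) / (2N - sum f_i)

with H the number of homozygous typed loci, N the number of typed
(polymorphic) loci used, and the sum running over the 2N carried allele
copies' population frequencies.  IR lies in [-1, 1]; its expectation over
offspring approximates the pedigree inbreeding coefficient F.  An observed
mean offspring IR is tested against the distribution of mean IRs of
offspring simulated under random mating of the sampled adults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeTable, IndividualMeta
from .qc import AlleleFrequencyTable

__all__ = [
    "internal_relatedness",
    "ir_vector",
    "ir_random_mating_null",
    "ir_locus_subset",
    "ir_covariate_summary",
    "IRResult",
    "CovariateSummary",
]


def _locus_arrays(freqs: AlleleFrequencyTable, loci: Sequence[str]):
    """Per-locus frequency lookups restricted to polymorphic loci."""
    out = {}
    for locus in loci:
        if locus not in freqs.freqs:
            continue
        fmap = freqs[locus]
        if len(fmap) < 2:
            continue  # monomorphic loci carry no IR information
        out[locus] = fmap
    return out


def internal_relatedness(
    calls: np.ndarray,
    freqs: AlleleFrequencyTable,
    loci: Sequence[str],
) -> float:
    """IR of one individual from its (n_loci, 2) call array.

    Monomorphic and missing loci are excluded, with N adjusted; alleles
    absent from the reference frequency table (private to the tested
    individual) count with frequency 0.  Raises when no usable locus
    remains (denominator zero).
    """
    fmaps = _locus_arrays(freqs, loci)
    H = 0
    N = 0
    sum_f = 0.0
    for l, locus in enumerate(loci):
        if locus not in fmaps:
            continue
        a, b = calls[l]
        if a == MISSING:
            continue
        fmap = fmaps[locus]
        N += 1
        H += int(a == b)
        sum_f += fmap.get(int(a), 0.0) + fmap.get(int(b), 0.0)
    denom = 2.0 * N - sum_f
    if N == 0 or denom <= 0:
        raise ValueError("IR undefined: no typed polymorphic locus")
    return (2.0 * H - sum_f) / denom


def ir_vector(
    table: GenotypeTable,
    freqs: AlleleFrequencyTable | None = None,
    individuals: Sequence[str] | None = None,
    loci: Sequence[str] | None = None,
) -> pd.Series:
    """IR per individual as a pandas Series."""
    from .qc import allele_frequencies

    if freqs is None:
        freqs = allele_frequencies(table)
    if individuals is None:
        individuals = table.individuals
    if loci is None:
        loci = table.loci
    sub = table.subset_individuals(individuals).subset_loci(loci)
    vals = [
        internal_relatedness(sub.calls[i], freqs, list(loci))
        for i in range(sub.n_individuals)
    ]
    return pd.Series(vals, index=list(individuals), name="IR")


@dataclass
class IRResult:
    observed_mean: float
    observed_ci95: tuple[float, float]
    null_means: np.ndarray
    p: float
    n_iter: int
    n_offspring_per_iter: int


def ir_random_mating_null(
    table: GenotypeTable,
    males: Sequence[str],
    females: Sequence[str],
    observed_ir: Sequence[float],
    freqs: AlleleFrequencyTable | None = None,
    n_iter: int = 1000,
    n_offspring_per_iter: int | None = None,
    seed: int | None = None,
    two_sided: bool = False,
) -> IRResult:
    """Monte Carlo random-mating null for mean offspring IR.

    Each iteration draws ``n_offspring_per_iter`` (male, female) pairs
    uniformly with replacement from the sampled adults, produces one
    offspring per pair by Mendelian sampling from the parental genotypes
    (loci missing in either parent skipped, N adjusted), and records the
    mean simulated IR.  The one-sided p (default; inbreeding = elevated IR)
    is the add-one-rule fraction of iterations whose simulated mean is at
    least the observed mean.
    """
    from .qc import allele_frequencies

    if freqs is None:
        freqs = allele_frequencies(table)
    if len(males) == 0 or len(females) == 0:
        raise ValueError("need at least one genotyped male and female")
    observed_ir = np.asarray(observed_ir, dtype=float)
    obs_mean = float(observed_ir.mean())
    if n_offspring_per_iter is None:
        n_offspring_per_iter = len(observed_ir)
    rng = np.random.default_rng(seed)
    fmaps = _locus_arrays(freqs, table.loci)
    loci_idx = [l for l, locus in enumerate(table.loci) if locus in fmaps]
    midx = np.array([table.individuals.index(m) for m in males])
    fidx = np.array([table.individuals.index(f) for f in females])
    n_tot = n_iter * n_offspring_per_iter
    sires = table.calls[rng.choice(midx, size=n_tot)]
    dams = table.calls[rng.choice(fidx, size=n_tot)]
    # per offspring per locus: one allele from each parent
    num = np.zeros(n_tot)
    den = np.zeros(n_tot)
    for l in loci_idx:
        locus = table.loci[l]
        fmap = fmaps[locus]
        s = sires[:, l, :]
        d = dams[:, l, :]
        ok = (s[:, 0] != MISSING) & (d[:, 0] != MISSING)
        a = np.where(rng.random(n_tot) < 0.5, s[:, 0], s[:, 1])
        b = np.where(rng.random(n_tot) < 0.5, d[:, 0], d[:, 1])
        freq_lookup = np.vectorize(lambda x: fmap.get(int(x), 0.0))
        fa = np.where(ok, freq_lookup(np.where(ok, a, next(iter(fmap)))), 0.0)
        fb = np.where(ok, freq_lookup(np.where(ok, b, next(iter(fmap)))), 0.0)
        hom = (a == b) & ok
        num += 2.0 * hom - (fa + fb)
        den += np.where(ok, 2.0, 0.0) - (fa + fb)
    with np.errstate(invalid="ignore"):
        ir = num / den
    ir = ir.reshape(n_iter, n_offspring_per_iter)
    null_means = np.nanmean(ir, axis=1)
    if two_sided:
        centre = float(np.mean(null_means))
        b = int(np.sum(np.abs(null_means - centre) >= abs(obs_mean - centre) - 1e-12))
    else:
        b = int(np.sum(null_means >= obs_mean - 1e-12))
    p = (b + 1) / (n_iter + 1)
    sem = observed_ir.std(ddof=1) / np.sqrt(len(observed_ir)) if len(observed_ir) > 1 else 0.0
    ci = (obs_mean - 1.96 * sem, obs_mean + 1.96 * sem)
    return IRResult(
        observed_mean=obs_mean,
        observed_ci95=ci,
        null_means=null_means,
        p=p,
        n_iter=n_iter,
        n_offspring_per_iter=n_offspring_per_iter,
    )


def ir_locus_subset(
    table: GenotypeTable,
    freqs: AlleleFrequencyTable | None = None,
    min_alleles: int = 5,
    individuals: Sequence[str] | None = None,
) -> tuple[pd.Series, list[str]]:
    """IR recomputed on the loci with at least ``min_alleles`` alleles.

    A robustness check against low-diversity loci inflating IR; returns the
    per-individual IR on the restricted panel and the loci retained.
    """
    from .qc import allele_frequencies

    if freqs is None:
        freqs = allele_frequencies(table)
    keep = [l for l in table.loci if l in freqs.freqs and len(freqs[l]) >= min_alleles]
    if not keep:
        raise ValueError(f"no locus has >= {min_alleles} alleles")
    return ir_vector(table, freqs, individuals=individuals, loci=keep), keep


@dataclass
class CovariateSummary:
    slope: float | None
    intercept: float | None
    r2: float | None
    p_regression: float | None
    stage_F: float | None
    stage_p: float | None
    cohort_F: float | None
    cohort_p: float | None


def ir_covariate_summary(
    ir: Mapping[str, float] | pd.Series,
    meta: Mapping[str, IndividualMeta],
) -> CovariateSummary:
    """OLS of IR on total length plus one-way ANOVAs by stage and cohort.

    Individuals lacking a covariate are dropped per analysis; a constant
    covariate yields None for that analysis.
    """
    ir = pd.Series(ir)
    lengths, vals = [], []
    for i, v in ir.items():
        m = meta.get(i)
        if m is not None and m.total_length_cm is not None:
            lengths.append(m.total_length_cm)
            vals.append(v)
    slope = intercept = r2 = p_reg = None
    if len(vals) >= 3 and len(set(lengths)) > 1:
        res = stats.linregress(lengths, vals)
        slope, intercept = float(res.slope), float(res.intercept)
        r2, p_reg = float(res.rvalue**2), float(res.pvalue)

    def anova(key):
        groups: dict = {}
        for i, v in ir.items():
            m = meta.get(i)
            val = getattr(m, key, None) if m else None
            if val is not None:
                groups.setdefault(val, []).append(v)
        groups = {k: v for k, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            return None, None
        F, p = stats.f_oneway(*groups.values())
        return float(F), float(p)

    stage_F, stage_p = anova("stage")
    cohort_F, cohort_p = anova("cohort_year")
    return CovariateSummary(slope, intercept, r2, p_reg, stage_F, stage_p, cohort_F, cohort_p)
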