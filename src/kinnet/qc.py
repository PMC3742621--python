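"""Per-locus marker quality control for microsatellite panels.

Implements the screening stage run before any kinship inference: allele
frequencies, observed and (small-sample unbiased) expected heterozygosity,
an exact conditional Hardy-Weinberg test (full enumeration on small
configuration spaces, Monte Carlo otherwise), null-allele estimators with a
one-sided homozygote-excess test, a genotypic linkage-disequilibrium
permutation test, Holm sequential-Bonferroni correction, duplicate-genotype
detection, and locus filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "AlleleFrequencyTable",
    "LocusSummary",
    "NullAlleleResult",
    "HolmResult",
    "allele_frequencies",
    "observed_heterozygosity",
    "expected_heterozygosity",
    "hwe_exact_test",
    "homozygote_excess_test",
    "null_allele_check",
    "ld_test",
    "sequential_bonferroni",
    "find_duplicate_genotypes",
    "filter_loci",
    "locus_summary",
    "qc_report",
]


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies plus the count of typed gene copies."""

    freqs: dict[str, dict[int, float]]
    n_gene_copies: dict[str, int]

    def loci(self) -> list[str]:
        return list(self.freqs)

    def __getitem__(self, locus: str) -> dict[int, float]:
        return self.freqs[locus]


@dataclass
class NullAlleleResult:
    """Null-allele frequency estimates and the homozygote-excess decision."""

    chakraborty: float | None
    brookfield1: float | None
    excess_p: float
    excess_flag: bool


@dataclass
class LocusSummary:
    locus: str
    n_typed: int
    k: int
    Ho: float
    He: float
    Fis: float | None
    hwe_p: float
    null_chakraborty: float | None
    null_brookfield1: float | None
    homozygote_excess_p: float
    flags: set = field(default_factory=set)


@dataclass
class HolmResult:
    pvalues: np.ndarray
    adjusted: np.ndarray
    reject: np.ndarray
    alpha: float


# ------------------------------------------------------------------ frequencies


def allele_frequencies(
    table: GenotypeTable, individuals: Sequence[str] | None = None
) -> AlleleFrequencyTable:
    """Allele frequencies per locus as allele count / typed gene copies.

    Missing calls contribute to neither numerator nor denominator.  Loci with
    zero typed calls in the subset are excluded with a warning.
    """
    if individuals is not None:
        table = table.subset_individuals(individuals)
    freqs: dict[str, dict[int, float]] = {}
    copies: dict[str, int] = {}
    for l, locus in enumerate(table.loci):
        calls = table.calls[:, l, :]
        alleles = calls[calls != MISSING]
        if alleles.size == 0:
            warnings.warn(f"locus {locus!r}: no typed calls, excluded from frequencies")
            continue
        vals, counts = np.unique(alleles, return_counts=True)
        n = int(alleles.size)
        freqs[locus] = {int(a): c / n for a, c in zip(vals, counts)}
        copies[locus] = n
    return AlleleFrequencyTable(freqs, copies)


def observed_heterozygosity(calls: np.ndarray) -> float:
    """Fraction of typed individuals heterozygous; ``calls`` is (n, 2)."""
    typed = calls[:, 0] != MISSING
    if not typed.any():
        raise ValueError("no typed individuals")
    c = calls[typed]
    return float(np.mean(c[:, 0] != c[:, 1]))


def expected_heterozygosity(calls: np.ndarray, unbiased: bool = True) -> float:
    """Expected heterozygosity 1 - sum p^2, small-sample corrected by 2n/(2n-1)."""
    typed = calls[:, 0] != MISSING
    alleles = calls[typed].ravel()
    n2 = alleles.size
    if n2 == 0:
        raise ValueError("no typed individuals")
    _, counts = np.unique(alleles, return_counts=True)
    p = counts / n2
    he = 1.0 - float(np.sum(p**2))
    if unbiased and n2 > 1:
        he *= n2 / (n2 - 1)
    return he


# ------------------------------------------------------------- HWE exact test


def _table_logprob_terms(het_count: int, genotype_counts: np.ndarray) -> float:
    """Non-constant part of the Levene conditional log-probability of a
    genotype table given its allele counts: H*log2 - sum log(n_ij!)."""
    return het_count * np.log(2.0) - float(np.sum(gammaln(genotype_counts + 1.0)))


def _enumerate_tables(allele_counts: np.ndarray, cap: int):
    """Lazily enumerate genotype-count tables consistent with allele counts.

    Cells are visited row by row ((0,0),(0,1),...,(0,k-1),(1,1),...); after
    cell (i, k-1) allele i can no longer be placed, which prunes the search.
    Yields (het_count, log-probability term).  Raises ``OverflowError`` once
    more than ``cap`` tables have been produced.
    """
    k = len(allele_counts)
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    produced = 0

    def rec(idx: int, remaining: tuple, het: int, log_fact: float):
        nonlocal produced
        if idx == len(cells):
            if all(r == 0 for r in remaining):
                produced += 1
                if produced > cap:
                    raise OverflowError("enumeration cap exceeded")
                yield het, het * np.log(2.0) - log_fact
            return
        i, j = cells[idx]
        max_n = remaining[i] // 2 if i == j else min(remaining[i], remaining[j])
        for n in range(int(max_n), -1, -1):
            rem = list(remaining)
            if i == j:
                rem[i] -= 2 * n
            else:
                rem[i] -= n
                rem[j] -= n
            if j == k - 1 and rem[i] != 0:
                continue  # allele i stranded
            yield from rec(
                idx + 1,
                tuple(rem),
                het + (0 if i == j else n),
                log_fact + float(gammaln(n + 1.0)),
            )

    yield from rec(0, tuple(int(c) for c in allele_counts), 0, 0.0)


def _mc_pair_stats(alleles: np.ndarray, k: int, m: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Randomly re-pair gene copies ``m`` times; return per-sample
    (log-probability term, heterozygote count)."""
    n2 = alleles.size
    tiled = np.tile(alleles, (m, 1))
    shuffled = rng.permuted(tiled, axis=1)
    a = shuffled[:, 0::2]
    b = shuffled[:, 1::2]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    het = (lo != hi).sum(axis=1)
    code = lo * k + hi
    counts = np.zeros((m, k * k), dtype=np.int32)
    rows = np.repeat(np.arange(m), n2 // 2)
    np.add.at(counts, (rows.ravel(), code.ravel()), 1)
    logp = het * np.log(2.0) - np.sum(gammaln(counts + 1.0), axis=1)
    return logp, het


def hwe_exact_test(
    calls: np.ndarray,
    n_mc: int = 100_000,
    seed: int | None = None,
    max_enum_tables: int = 200_000,
) -> float:
    """Exact conditional Hardy-Weinberg test for one locus.

    ``calls`` is the (n, 2) genotype array of the locus (missing rows
    dropped).  The test conditions on the observed allele counts and orders
    configurations by their Levene conditional probability; the p-value sums
    tables no more probable than the observed one.  The full configuration
    space is enumerated while it stays below ``max_enum_tables``; otherwise a
    Monte Carlo version re-pairs gene copies ``n_mc`` times and applies the
    add-one rule p = (b+1)/(m+1).
    """
    typed = calls[:, 0] != MISSING
    c = calls[typed]
    if c.shape[0] < 2:
        raise ValueError("need at least 2 typed individuals")
    alleles_obs = c.ravel()
    vals, allele_counts = np.unique(alleles_obs, return_counts=True)
    k = len(vals)
    if k == 1:
        return 1.0
    recode = {int(v): i for i, v in enumerate(vals)}
    lo = np.vectorize(recode.get)(np.minimum(c[:, 0], c[:, 1]))
    hi = np.vectorize(recode.get)(np.maximum(c[:, 0], c[:, 1]))
    obs_counts = np.zeros(k * k, dtype=np.int64)
    np.add.at(obs_counts, lo * k + hi, 1)
    obs_het = int(np.sum(lo != hi))
    obs_logp = _table_logprob_terms(obs_het, obs_counts)
    tol = 1e-9
    try:
        all_logp = []
        hit_logp = []
        for _het, logp in _enumerate_tables(allele_counts, max_enum_tables):
            all_logp.append(logp)
            if logp <= obs_logp + tol:
                hit_logp.append(logp)
        from scipy.special import logsumexp

        return float(np.exp(logsumexp(hit_logp) - logsumexp(all_logp)))
    except OverflowError:
        rng = np.random.default_rng(seed)
        coded = np.array([recode[int(a)] for a in alleles_obs])
        logp_sim, _ = _mc_pair_stats(coded, k, n_mc, rng)
        b = int(np.sum(logp_sim <= obs_logp + tol))
        return (b + 1) / (n_mc + 1)


def homozygote_excess_test(
    calls: np.ndarray,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> float:
    """One-sided Monte Carlo test for heterozygote deficit at one locus.

    Conditions on allele counts like the exact HWE test but the statistic is
    the heterozygote count: p = P(simulated het count <= observed).
    """
    typed = calls[:, 0] != MISSING
    c = calls[typed]
    if c.shape[0] < 2:
        return 1.0
    alleles_obs = c.ravel()
    vals = np.unique(alleles_obs)
    if len(vals) == 1:
        return 1.0
    recode = {int(v): i for i, v in enumerate(vals)}
    coded = np.array([recode[int(a)] for a in alleles_obs])
    obs_het = int(np.sum(c[:, 0] != c[:, 1]))
    rng = np.random.default_rng(seed)
    _, het_sim = _mc_pair_stats(coded, len(vals), n_mc, rng)
    b = int(np.sum(het_sim <= obs_het))
    return (b + 1) / (n_mc + 1)


# ------------------------------------------------------------- null alleles


def null_allele_check(
    calls: np.ndarray,
    alpha: float = 0.05,
    n_mc: int = 10_000,
    seed: int | None = None,
) -> NullAlleleResult:
    """Null-allele frequency estimators plus a homozygote-excess flag.

    Chakraborty: r = (He - Ho) / (He + Ho); Brookfield-1: r = (He - Ho) /
    (1 + He).  The flag is raised when the one-sided homozygote-excess test
    rejects at ``alpha``.  With He = 0 the estimators are undefined (None)
    and the flag stays False.
    """
    ho = observed_heterozygosity(calls)
    he = expected_heterozygosity(calls)
    if he <= 0:
        return NullAlleleResult(None, None, 1.0, False)
    chak = (he - ho) / (he + ho) if (he + ho) > 0 else None
    brook = (he - ho) / (1.0 + he)
    p = homozygote_excess_test(calls, n_mc=n_mc, seed=seed)
    return NullAlleleResult(chak, brook, p, bool(p < alpha))


# ------------------------------------------------------------------------- LD


def ld_test(
    table: GenotypeTable,
    locus_a: str,
    locus_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> float:
    """Genotypic linkage-disequilibrium permutation test between two loci.

    The statistic is the log-likelihood-ratio (G) statistic of the two-locus
    genotype contingency table over individuals typed at both loci; the null
    is built by permuting one locus's genotype column; p uses the add-one
    rule.  Returns 1.0 when either locus is monomorphic among shared
    individuals.
    """
    ca = table.locus_calls(locus_a)
    cb = table.locus_calls(locus_b)
    shared = (ca[:, 0] != MISSING) & (cb[:, 0] != MISSING)
    if shared.sum() < 2:
        raise ValueError("need >=2 individuals typed at both loci")
    ca, cb = ca[shared], cb[shared]

    def codes(c):
        pairs, inv = np.unique(c, axis=0, return_inverse=True)
        return inv, len(pairs)

    ga, ka = codes(ca)
    gb, kb = codes(cb)
    if ka == 1 or kb == 1:
        return 1.0

    n = len(ga)

    def g_stat(b_col: np.ndarray) -> float:
        joint = np.zeros((ka, kb))
        np.add.at(joint, (ga, b_col), 1.0)
        ra = joint.sum(axis=1, keepdims=True)
        rb = joint.sum(axis=0, keepdims=True)
        expected = ra @ rb / n
        mask = joint > 0
        return 2.0 * float(np.sum(joint[mask] * np.log(joint[mask] / expected[mask])))

    obs = g_stat(gb)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(gb, (n_perm, 1)), axis=1)
    b = 0
    for row in perms:
        if g_stat(row) >= obs - 1e-12:
            b += 1
    return (b + 1) / (n_perm + 1)


# --------------------------------------------------------- multiple testing


def sequential_bonferroni(pvalues: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Holm step-down (sequential Bonferroni) correction.

    Returns adjusted p-values (monotone non-decreasing in sorted order,
    capped at 1) and reject decisions at family-wise level ``alpha``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    # Holm adjusted p: running max of min(1, (m-i) * p_(i)) over sorted p
    adj_sorted = np.maximum.accumulate(np.minimum((m - np.arange(m)) * p[order], 1.0))
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted < alpha
    return HolmResult(p, adjusted, reject, alpha)


# ------------------------------------------------------------- duplicates


def find_duplicate_genotypes(
    table: GenotypeTable,
    max_mismatch: int = 0,
    min_shared_loci: int = 5,
):
    """Find pairs of individuals with (near-)identical multilocus genotypes.

    Returns ``(matches, incomparable)``: matches are (id_a, id_b, mismatches,
    shared_loci) with mismatches <= ``max_mismatch`` over loci typed in both;
    pairs sharing fewer than ``min_shared_loci`` typed loci are excluded from
    matching and reported separately.
    """
    calls = table.calls
    typed = table.typed_mask()
    n = table.n_individuals
    eq = (calls[:, None, :, 0] == calls[None, :, :, 0]) & (
        calls[:, None, :, 1] == calls[None, :, :, 1]
    )
    both = typed[:, None, :] & typed[None, :, :]
    mism = (~eq & both).sum(axis=2)
    shared = both.sum(axis=2)
    matches, incomparable = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] < min_shared_loci:
                incomparable.append((table.individuals[i], table.individuals[j]))
            elif mism[i, j] <= max_mismatch:
                matches.append(
                    (
                        table.individuals[i],
                        table.individuals[j],
                        int(mism[i, j]),
                        int(shared[i, j]),
                    )
                )
    return matches, incomparable


def filter_loci(table: GenotypeTable, flagged: Sequence[str]) -> GenotypeTable:
    """Return a copy of ``table`` without the flagged loci."""
    flagged = set(flagged)
    unknown = flagged - set(table.loci)
    if unknown:
        raise ValueError(f"unknown loci: {sorted(unknown)}")
    keep = [l for l in table.loci if l not in flagged]
    if not keep:
        warnings.warn("all loci removed; returning empty table")
    return table.subset_loci(keep)


# ------------------------------------------------------------------ summary


def locus_summary(
    table: GenotypeTable,
    seed: int | None = None,
    n_mc: int = 20_000,
) -> list[LocusSummary]:
    """Per-locus QC summary (no multiple-testing flags; see :func:`qc_report`)."""
    if table.n_individuals == 0 or table.n_loci == 0:
        raise ValueError("empty genotype table")
    out = []
    for idx, locus in enumerate(table.loci):
        calls = table.locus_calls(locus)
        typed = calls[:, 0] != MISSING
        n_typed = int(typed.sum())
        alleles = calls[typed].ravel()
        k = int(len(np.unique(alleles))) if n_typed else 0
        ho = observed_heterozygosity(calls)
        he = expected_heterozygosity(calls)
        fis = (1.0 - ho / he) if he > 0 else None
        sub = None if seed is None else seed + idx
        hwe_p = hwe_exact_test(calls, n_mc=n_mc, seed=sub) if k > 1 else 1.0
        nulls = null_allele_check(calls, n_mc=n_mc, seed=sub)
        out.append(
            LocusSummary(
                locus=locus,
                n_typed=n_typed,
                k=k,
                Ho=ho,
                He=he,
                Fis=fis,
                hwe_p=hwe_p,
                null_chakraborty=nulls.chakraborty,
                null_brookfield1=nulls.brookfield1,
                homozygote_excess_p=nulls.excess_p,
            )
        )
    return out


def qc_report(
    table: GenotypeTable,
    alpha: float = 0.05,
    seed: int | None = None,
    n_mc: int = 20_000,
) -> list[LocusSummary]:
    """Locus summaries with family-wise flags.

    Holm sequential-Bonferroni correction is applied across loci separately
    for the HWE test and the homozygote-excess test; ``null_allele_suspect``
    and ``hwe_deviation`` flags reflect the corrected decisions.
    """
    summaries = locus_summary(table, seed=seed, n_mc=n_mc)
    hwe = sequential_bonferroni([s.hwe_p for s in summaries], alpha)
    excess = sequential_bonferroni([s.homozygote_excess_p for s in summaries], alpha)
    for i, s in enumerate(summaries):
        if hwe.reject[i]:
            s.flags.add("hwe_deviation")
        if excess.reject[i]:
            s.flags.add("null_allele_suspect")
    return summaries
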