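"""Ground-truthed pedigree and genotype simulation.

Emulates the sampling situation of a small, closed island shark population
genotyped at microsatellites: a modest adult pool with a skewed, polygamous
mating system (polyandrous females, biennial female breeding, male
reproductive skew, nursery-site fidelity), partial sampling of adults,
near-complete sampling of juvenile cohorts, and an observation layer adding
genotyping error, locus-specific null alleles, and missing data.

Two entry points:

* :func:`simulate_founders` / :func:`simulate_pedigree` /
  :func:`apply_observation_model` — the general simulator driven by a
  :class:`PedigreeSpec`;
* :func:`make_study_fixture` — a deterministic study-shaped dataset: 33
  sampled adults (one an unrelated outgroup female, the rest in small
  first-order family clusters), 52 sampled juveniles in 29 litters from 41
  true breeders of whom 12 are sampled, 16 loci of which 2 carry planted
  null alleles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import (
    GenotypeTable,
    IndividualMeta,
    MISSING,
    stage_from_length,
    write_genotypes,
    write_metadata,
)
from .qc import AlleleFrequencyTable

__all__ = [
    "NULL_ALLELE",
    "PedigreeSpec",
    "TruthSet",
    "StudyFixture",
    "simulate_founders",
    "simulate_pedigree",
    "apply_observation_model",
    "make_study_fixture",
    "pedigree_kinship",
    "pedigree_relatedness",
]

#: Reserved allele code for a non-amplifying (null) allele.
NULL_ALLELE = 999

_DEFAULT_LITTER_P = np.array(
    [0.26, 0.22, 0.16, 0.12, 0.08, 0.05, 0.04, 0.03, 0.02, 0.01, 0.005, 0.003, 0.002]
)
_DEFAULT_SIRES_P = {1: 0.25, 2: 0.5, 3: 0.25}


@dataclass
class PedigreeSpec:
    """Parameters of the simulated population and observation process.

    Defaults follow the study system: ~20 founder males and ~21 founder
    females, four breeding seasons, biennial female cycles, litters of 1-13
    pups (decreasing distribution, mean ~3), 1-3 sires per litter with
    polyandry in most multi-pup litters, concentrated male reproductive
    success, four nursery sites with strong female site fidelity, 16 loci
    with 2-15 alleles each and a 1% genotyping error rate.
    """

    n_founder_males: int = 20
    n_founder_females: int = 21
    n_breeding_years: int = 4
    start_year: int = 2006
    female_cycle: str = "biennial"  # biennial | annual | mixed
    cycle_exception_prob: float = 0.1
    breeding_prob: float = 0.9
    litter_size_probs: np.ndarray = field(
        default_factory=lambda: _DEFAULT_LITTER_P / _DEFAULT_LITTER_P.sum()
    )
    sires_per_litter_probs: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_SIRES_P)
    )
    male_skew: float = 0.5  # Dirichlet concentration; smaller = stronger skew
    nursery_sites: tuple[str, ...] = ("Moorea", "Tetiaroa", "Tahaa", "Rangiroa")
    site_fidelity: float = 0.9
    adult_sampling_fraction: float = 0.7
    juvenile_sampling_fraction: float = 1.0
    n_loci: int = 16
    alleles_per_locus: tuple[int, ...] | None = None  # default: 2..15 spread
    freq_profile: str = "empirical"  # empirical | equifrequent
    error_rate: float = 0.01
    null_allele_freqs: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int | None = None

    def locus_names(self) -> list[str]:
        return [f"Na{i + 1:02d}" for i in range(self.n_loci)]

    def allele_counts(self) -> list[int]:
        if self.alleles_per_locus is not None:
            return list(self.alleles_per_locus)
        # spread 2..15 across the panel, most loci moderately polymorphic
        base = [15, 13, 12, 11, 10, 9, 9, 8, 7, 7, 6, 5, 4, 2]
        counts = [base[i % len(base)] for i in range(self.n_loci)]
        return counts


@dataclass
class TruthSet:
    """Complete simulation truth: pedigree, genotypes, sampling status."""

    pedigree: pd.DataFrame  # id, mother, father, cohort_year, nursery
    sex: dict[str, str]
    founders: list[str]
    genotypes_true: GenotypeTable  # all individuals, pre-error (nulls visible)
    true_freqs: AlleleFrequencyTable
    sampled: list[str]
    meta: dict[str, IndividualMeta]
    version: str = "1"

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        row = self.pedigree[self.pedigree["id"] == individual]
        if row.empty:
            return None, None
        r = row.iloc[0]
        return r["mother"], r["father"]


# ---------------------------------------------------------------- founders


def _locus_frequencies(spec: PedigreeSpec, rng) -> AlleleFrequencyTable:
    freqs: dict[str, dict[int, float]] = {}
    copies: dict[str, int] = {}
    for locus, k in zip(spec.locus_names(), spec.allele_counts()):
        codes = [100 + 2 * i for i in range(k)]
        if spec.freq_profile == "equifrequent":
            p = np.full(k, 1.0 / k)
        else:
            p = rng.dirichlet(np.full(k, 1.5))
            p = np.maximum(p, 0.015)
            p /= p.sum()
        fmap = {c: float(v) for c, v in zip(codes, p)}
        q = spec.null_allele_freqs.get(locus, 0.0)
        if q > 0:
            fmap = {c: v * (1.0 - q) for c, v in fmap.items()}
            fmap[NULL_ALLELE] = q
        freqs[locus] = fmap
        copies[locus] = 0
    return AlleleFrequencyTable(freqs, copies)


def _draw_genotypes(freqs: AlleleFrequencyTable, n: int, rng) -> np.ndarray:
    loci = freqs.loci()
    calls = np.empty((n, len(loci), 2), dtype=np.int64)
    for l, locus in enumerate(loci):
        alleles = np.array(list(freqs[locus]))
        p = np.array([freqs[locus][int(a)] for a in alleles])
        calls[:, l, :] = alleles[rng.choice(len(alleles), size=(n, 2), p=p)]
    return np.sort(calls, axis=2)


def simulate_founders(
    spec: PedigreeSpec, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, AlleleFrequencyTable, dict[str, str]]:
    """Draw founder genotypes from HWE at the spec's allele frequencies.

    Returns the founder genotype table (males then females), the true
    frequency table, and the sex map.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    freqs = _locus_frequencies(spec, rng)
    males = [f"M{i + 1:02d}" for i in range(spec.n_founder_males)]
    females = [f"F{i + 1:02d}" for i in range(spec.n_founder_females)]
    ids = males + females
    calls = _draw_genotypes(freqs, len(ids), rng)
    table = GenotypeTable(ids, freqs.loci(), calls)
    sex = {m: "M" for m in males} | {f: "F" for f in females}
    return table, freqs, sex


# ---------------------------------------------------------------- pedigree


def _gene_drop(mother: np.ndarray, father: np.ndarray, rng) -> np.ndarray:
    """One offspring's calls by Mendelian sampling from two (L, 2) parents."""
    L = mother.shape[0]
    a = mother[np.arange(L), rng.integers(0, 2, L)]
    b = father[np.arange(L), rng.integers(0, 2, L)]
    return np.sort(np.stack([a, b], axis=1), axis=1)


def simulate_pedigree(
    spec: PedigreeSpec,
    founders: GenotypeTable,
    freqs: AlleleFrequencyTable,
    sex: Mapping[str, str],
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Gene-drop offspring through the spec's mating system.

    Per breeding year, cycle-eligible females each produce at most one
    litter; sires are drawn by skew-weighted sampling without replacement
    within a litter; nursery sites follow female fidelity.  Offspring
    genotypes are exact Mendelian draws from the parental genotypes.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    males = [i for i in founders.individuals if sex[i] == "M"]
    females = [i for i in founders.individuals if sex[i] == "F"]
    if not males:
        raise ValueError("no founder males")
    male_w = rng.dirichlet(np.full(len(males), spec.male_skew))
    phase = {f: int(rng.integers(0, 2)) for f in females}
    home = {f: spec.nursery_sites[rng.integers(len(spec.nursery_sites))] for f in females}
    fidx = {ind: i for i, ind in enumerate(founders.individuals)}
    rows = []
    off_calls = []
    off_ids = []
    off_sex = {}
    litter_sizes = np.arange(1, 14)
    for t in range(spec.n_breeding_years):
        year = spec.start_year + t
        for f in females:
            if spec.female_cycle == "biennial":
                eligible = t % 2 == phase[f]
            elif spec.female_cycle == "annual":
                eligible = True
            else:  # mixed: biennial with exceptions
                eligible = (t % 2 == phase[f]) or (
                    rng.random() < spec.cycle_exception_prob
                )
            if not eligible or rng.random() > spec.breeding_prob:
                continue
            size = int(rng.choice(litter_sizes, p=spec.litter_size_probs))
            ks = sorted(spec.sires_per_litter_probs)
            pk = np.array([spec.sires_per_litter_probs[k] for k in ks], dtype=float)
            n_sires = int(np.asarray(ks)[rng.choice(len(ks), p=pk / pk.sum())])
            n_sires = min(n_sires, size, len(males))
            sires = list(
                np.asarray(males)[
                    rng.choice(len(males), size=n_sires, replace=False, p=male_w)
                ]
            )
            # each sire fathers at least one pup; remainder assigned at random
            pup_sires = sires + [
                sires[rng.integers(n_sires)] for _ in range(size - n_sires)
            ]
            rng.shuffle(pup_sires)
            if rng.random() < spec.site_fidelity:
                site = home[f]
            else:
                site = spec.nursery_sites[rng.integers(len(spec.nursery_sites))]
            for p, sire in enumerate(pup_sires):
                oid = f"J{year % 100:02d}_{len(off_ids) + 1:03d}"
                off_ids.append(oid)
                off_sex[oid] = "M" if rng.random() < 0.5 else "F"
                off_calls.append(
                    _gene_drop(
                        founders.calls[fidx[f]], founders.calls[fidx[sire]], rng
                    )
                )
                rows.append(
                    {
                        "id": oid,
                        "mother": f,
                        "father": sire,
                        "cohort_year": year,
                        "nursery": site,
                    }
                )
    all_ids = list(founders.individuals) + off_ids
    all_calls = np.concatenate(
        [founders.calls, np.array(off_calls).reshape(len(off_ids), founders.n_loci, 2)]
    ) if off_ids else founders.calls
    genotypes_true = GenotypeTable(all_ids, founders.loci, all_calls)
    sampled = [
        i
        for i in founders.individuals
        if rng.random() < spec.adult_sampling_fraction
    ] + [o for o in off_ids if rng.random() < spec.juvenile_sampling_fraction]
    last_year = spec.start_year + spec.n_breeding_years - 1
    meta: dict[str, IndividualMeta] = {}
    for i in founders.individuals:
        meta[i] = IndividualMeta(
            id=i,
            sex=sex[i],
            total_length_cm=float(np.round(rng.uniform(240, 310), 1)),
            stage="mature",
            group="adult",
            site=spec.nursery_sites[0],
        )
    ped = pd.DataFrame(rows, columns=["id", "mother", "father", "cohort_year", "nursery"])
    for r in rows:
        age = last_year - r["cohort_year"]
        lo, hi = [(60, 84), (85, 99), (100, 114), (115, 129)][min(age, 3)]
        length = float(np.round(rng.uniform(lo, hi), 1))
        meta[r["id"]] = IndividualMeta(
            id=r["id"],
            sex=off_sex[r["id"]],
            total_length_cm=length,
            stage=stage_from_length(length),
            group="juvenile",
            site=r["nursery"],
            cohort_year=int(r["cohort_year"]),
        )
    sexes = dict(sex) | off_sex
    return TruthSet(
        pedigree=ped,
        sex=sexes,
        founders=list(founders.individuals),
        genotypes_true=genotypes_true,
        true_freqs=freqs,
        sampled=sampled,
        meta=meta,
    )


# ------------------------------------------------------------ observation


def apply_observation_model(
    truth: TruthSet,
    spec: PedigreeSpec,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeTable, dict[str, IndividualMeta]]:
    """Observed genotypes of the sampled individuals.

    Per individual-locus cell, with probability ``error_rate`` the call is
    replaced by an independent HWE draw; at null-allele loci a heterozygote
    carrying the null appears homozygous for its visible allele and a
    null/null homozygote is missing; additional random missingness applies
    last.  Metadata is restricted to the sampled individuals.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    src = truth.genotypes_true.subset_individuals(truth.sampled)
    calls = src.calls.copy()
    n, L, _ = calls.shape
    if spec.error_rate > 0:
        err = rng.random((n, L)) < spec.error_rate
        if err.any():
            redraw = _draw_genotypes(truth.true_freqs, n, rng)
            calls[err] = redraw[err]
    # null-allele masking
    for l, locus in enumerate(src.loci):
        if NULL_ALLELE not in truth.true_freqs[locus]:
            continue
        a, b = calls[:, l, 0], calls[:, l, 1]
        both = (a == NULL_ALLELE) & (b == NULL_ALLELE)
        one = (b == NULL_ALLELE) & ~both  # null sorts last (code 999)
        calls[one, l, 1] = calls[one, l, 0]
        calls[both, l, :] = MISSING
    if spec.missing_rate > 0:
        miss = rng.random((n, L)) < spec.missing_rate
        calls[miss] = MISSING
    observed = GenotypeTable(src.individuals, src.loci, calls)
    meta = {i: truth.meta[i] for i in src.individuals if i in truth.meta}
    return observed, meta


# ------------------------------------------------------- pedigree kinship


def pedigree_kinship(parents: Mapping[str, tuple[str | None, str | None]]):
    """Return a memoised kinship-coefficient function phi(a, b).

    ``parents`` maps individual -> (mother, father); founders map to
    (None, None).  Relatedness r = 2 * phi for non-inbred pairs.
    """
    cache: dict[tuple[str, str], float] = {}
    order: dict[str, int] = {}

    def depth(x: str) -> int:
        if x in order:
            return order[x]
        m, f = parents.get(x, (None, None))
        d = 0 if m is None and f is None else 1 + max(
            depth(m) if m else 0, depth(f) if f else 0
        )
        order[x] = d
        return d

    def phi(a: str, b: str) -> float:
        if a == b:
            m, f = parents.get(a, (None, None))
            if m is None or f is None:
                return 0.5
            return 0.5 * (1.0 + phi(m, f))
        key = (a, b) if a <= b else (b, a)
        if key in cache:
            return cache[key]
        # recurse on the individual further from the founders
        x, y = (a, b) if depth(a) >= depth(b) else (b, a)
        m, f = parents.get(x, (None, None))
        if m is None and f is None:
            val = 0.0
        else:
            val = 0.5 * ((phi(m, y) if m else 0.0) + (phi(f, y) if f else 0.0))
        cache[key] = val
        return val

    return phi


def pedigree_relatedness(truth: TruthSet, ids: Sequence[str]) -> pd.DataFrame:
    """True pairwise relatedness (2 * kinship) matrix for ``ids``."""
    parents = {
        r["id"]: (r["mother"], r["father"]) for _, r in truth.pedigree.iterrows()
    }
    phi = pedigree_kinship(parents)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = 2.0 * phi(ids[i], ids[j])
    np.fill_diagonal(out, np.nan)
    return pd.DataFrame(out, index=list(ids), columns=list(ids))


# ------------------------------------------------------------ study fixture


#: (mother index 1..21, year, litter size, number of sires)
_FIXTURE_LITTERS: list[tuple[int, int, int, int]] = [
    (1, 2006, 4, 3), (1, 2008, 3, 1),
    (2, 2007, 5, 3), (2, 2009, 1, 1),
    (3, 2006, 2, 1), (3, 2008, 1, 1),
    (4, 2007, 4, 2), (4, 2009, 1, 1),
    (5, 2006, 1, 1), (5, 2008, 4, 2),
    (6, 2007, 3, 2), (6, 2009, 1, 1),
    (7, 2006, 1, 1), (7, 2008, 1, 1),
    (8, 2007, 4, 2), (8, 2009, 1, 1),
    (9, 2006, 3, 2),
    (10, 2007, 1, 1), (11, 2008, 1, 1), (12, 2009, 1, 1),
    (13, 2006, 1, 1), (14, 2007, 1, 1), (15, 2008, 1, 1),
    (16, 2009, 1, 1), (17, 2006, 1, 1), (18, 2007, 1, 1),
    (19, 2008, 1, 1), (20, 2009, 1, 1), (21, 2006, 1, 1),
]


@dataclass
class StudyFixture:
    table: GenotypeTable
    meta: dict[str, IndividualMeta]
    truth: TruthSet
    null_loci: list[str]
    outgroup: str
    breeders: dict[str, list[str]]  # sampled/unsampled mothers/fathers
    paths: dict[str, Path] = field(default_factory=dict)


def _fixture_spec() -> PedigreeSpec:
    counts = [15, 13, 12, 11, 10, 9, 9, 8, 7, 7, 6, 5, 4, 3, 8, 6]
    spec = PedigreeSpec(
        n_loci=16,
        alleles_per_locus=tuple(counts),
        error_rate=0.01,
        missing_rate=0.0,
    )
    return spec


_FIXTURE_LOCI = [f"Na{i:02d}" for i in range(1, 15)] + ["LS15", "Cli107"]


def make_study_fixture(seed: int = 2013, out_dir=None) -> StudyFixture:
    """Deterministic study-shaped dataset with full ground truth.

    Structure: 33 sampled adults — ten parent+two-offspring family trios,
    one parent-offspring pair, and one unrelated outgroup female ``B4`` —
    plus 52 sampled juveniles born in 29 litters (2006-2009, four nursery
    sites) to 21 mothers and 20 fathers (41 breeders, 12 of them sampled:
    4 mothers, 8 fathers).  Sixteen loci; ``LS15`` and ``Cli107`` carry
    planted null alleles.  Writes GenePop, metadata CSV and truth JSON when
    ``out_dir`` is given; the same seed yields byte-identical files.
    """
    rng = np.random.default_rng(seed)
    spec = _fixture_spec()
    spec.null_allele_freqs = {}  # set after renaming loci below

    # --- locus frequencies (rename tail loci to the null-affected names)
    freqs0 = _locus_frequencies(spec, rng)
    name_map = dict(zip(spec.locus_names(), _FIXTURE_LOCI))
    freqs = AlleleFrequencyTable(
        {name_map[l]: dict(freqs0[l]) for l in freqs0.loci()},
        {name_map[l]: 0 for l in freqs0.loci()},
    )
    null_loci = ["LS15", "Cli107"]
    for locus, q in zip(null_loci, (0.25, 0.20)):
        fmap = {a: v * (1.0 - q) for a, v in freqs[locus].items()}
        fmap[NULL_ALLELE] = q
        freqs.freqs[locus] = fmap
    loci = list(freqs.loci())

    # --- sampled adults: 10 trios (parent + 2 adult offspring), 1 PO pair,
    # and the outgroup female B4; sexes arranged to give 13 M / 20 F.
    trio_parent_sex = ["M", "F", "M", "F", "M", "F", "M", "F", "M", "F"]
    trio_child_sex = [
        ("M", "F"), ("M", "F"), ("F", "F"), ("M", "M"), ("F", "F"),
        ("M", "F"), ("F", "F"), ("M", "F"), ("M", "F"), ("F", "F"),
    ]
    ids: list[str] = []
    sex: dict[str, str] = {}
    ped_rows: list[dict] = []
    virtual: list[str] = []
    mcount = fcount = 0

    def adult_id(s: str) -> str:
        nonlocal mcount, fcount
        if s == "M":
            mcount += 1
            return f"M{mcount:02d}"
        fcount += 1
        return f"F{fcount:02d}"

    trios: list[tuple[str, str, str]] = []
    for t in range(10):
        parent = adult_id(trio_parent_sex[t])
        co = f"V{t + 1:02d}"  # unsampled virtual co-parent
        virtual.append(co)
        c1 = adult_id(trio_child_sex[t][0])
        c2 = adult_id(trio_child_sex[t][1])
        mo, fa = (parent, co) if trio_parent_sex[t] == "F" else (co, parent)
        for c in (c1, c2):
            ped_rows.append(
                {"id": c, "mother": mo, "father": fa, "cohort_year": None, "nursery": None}
            )
        trios.append((parent, c1, c2))
        ids += [parent, c1, c2]
        sex |= {parent: trio_parent_sex[t], c1: trio_child_sex[t][0], c2: trio_child_sex[t][1]}
    pair_parent = adult_id("M")  # 13th male
    pair_child = adult_id("F")
    virtual.append("V11")
    ped_rows.append(
        {"id": pair_child, "mother": "V11", "father": pair_parent,
         "cohort_year": None, "nursery": None}
    )
    ids += [pair_parent, pair_child]
    sex |= {pair_parent: "M", pair_child: "F"}
    outgroup = "B4"
    ids.append(outgroup)
    sex[outgroup] = "F"
    assert sum(1 for i in ids if sex[i] == "M") == 13
    assert sum(1 for i in ids if sex[i] == "F") == 20

    # --- breeders: 4 sampled mothers, 8 sampled fathers among the trio/pair
    # adults (never B4); 17 + 12 unsampled founders.
    sampled_females = [i for i in ids if sex[i] == "F" and i != outgroup]
    sampled_males = [i for i in ids if sex[i] == "M"]
    sampled_mothers = [sampled_females[i] for i in (0, 4, 9, 14)]
    sampled_fathers = [sampled_males[i] for i in (0, 2, 4, 6, 8, 9, 11, 12)]
    unsampled_mothers = [f"UF{i + 1:02d}" for i in range(17)]
    unsampled_fathers = [f"UM{i + 1:02d}" for i in range(12)]
    mothers = sampled_mothers + unsampled_mothers  # 21, template indexes 1..21
    fathers = sampled_fathers + unsampled_fathers  # 20
    for u in unsampled_mothers:
        sex[u] = "F"
    for u in unsampled_fathers:
        sex[u] = "M"
    for v in virtual:
        sex[v] = "unknown"

    # --- assign fathers to litter-sire slots: 10 fathers sire >=2 litters
    capacities = {f: c for f, c in zip(fathers, [4, 4, 3, 3, 3, 3, 2, 2, 2, 2] + [1] * 10)}
    litter_sires: list[list[str]] = []
    for _, _, _, n_sires in sorted(_FIXTURE_LITTERS, key=lambda r: -r[3]):
        chosen: list[str] = []
        for f in sorted(capacities, key=lambda f: -capacities[f]):
            if capacities[f] > 0 and f not in chosen:
                chosen.append(f)
            if len(chosen) == n_sires:
                break
        for f in chosen:
            capacities[f] -= 1
        litter_sires.append(chosen)
    order = np.argsort([-r[3] for r in _FIXTURE_LITTERS], kind="stable")
    sires_of_litter: dict[int, list[str]] = {}
    for rank, lit_idx in enumerate(order):
        sires_of_litter[int(lit_idx)] = litter_sires[rank]

    # --- juveniles
    home = {m: spec.nursery_sites[i % 4] for i, m in enumerate(mothers)}
    jrows: list[dict] = []
    jids: list[str] = []
    for lit_idx, (mi, year, size, n_sires) in enumerate(_FIXTURE_LITTERS):
        mother = mothers[mi - 1]
        sires = sires_of_litter[lit_idx]
        pup_sires = list(sires) + [
            sires[int(rng.integers(len(sires)))] for _ in range(size - len(sires))
        ]
        rng.shuffle(pup_sires)
        site = home[mother]
        for sire in pup_sires:
            jid = f"J{year % 100:02d}_{len(jids) + 1:02d}"
            jids.append(jid)
            sex[jid] = "M" if rng.random() < 0.5 else "F"
            jrows.append(
                {"id": jid, "mother": mother, "father": sire,
                 "cohort_year": year, "nursery": site}
            )
    assert len(jids) == 52

    # --- genotypes: founders HWE, everyone else gene-dropped
    founder_ids = (
        [t[0] for t in trios] + [pair_parent, outgroup] + virtual
        + unsampled_mothers + unsampled_fathers
    )
    founder_calls = _draw_genotypes(freqs, len(founder_ids), rng)
    geno: dict[str, np.ndarray] = {
        i: c for i, c in zip(founder_ids, founder_calls)
    }
    all_ped = ped_rows + jrows
    for r in all_ped:
        geno[r["id"]] = _gene_drop(geno[r["mother"]], geno[r["father"]], rng)
    all_ids = founder_ids + [r["id"] for r in all_ped]
    genotypes_true = GenotypeTable(all_ids, loci, np.stack([geno[i] for i in all_ids]))

    # --- metadata
    last_year = 2009
    meta: dict[str, IndividualMeta] = {}
    groups = {0: "resident_moorea", 1: "resident_moorea", 2: "resident_moorea",
              3: "resident_moorea", 4: "nonresident", 5: "nonresident",
              6: "nonresident", 7: "nonresident", 8: "bora_resident",
              9: "bora_resident"}
    for t, (parent, c1, c2) in enumerate(trios):
        for i in (parent, c1, c2):
            meta[i] = IndividualMeta(
                id=i, sex=sex[i],
                total_length_cm=float(np.round(rng.uniform(240, 310), 1)),
                stage="mature", group=groups[t],
                site="BoraBora" if groups[t] == "bora_resident" else "Moorea",
            )
    for i in (pair_parent, pair_child):
        meta[i] = IndividualMeta(
            id=i, sex=sex[i],
            total_length_cm=float(np.round(rng.uniform(240, 310), 1)),
            stage="mature", group="nonresident", site="Moorea",
        )
    meta[outgroup] = IndividualMeta(
        id=outgroup, sex="F",
        total_length_cm=float(np.round(rng.uniform(240, 310), 1)),
        stage="mature", group="bora_resident", site="BoraBora",
    )
    for r in jrows:
        age = last_year - r["cohort_year"]
        lo, hi = [(60, 84), (85, 99), (100, 114), (115, 129)][min(age, 3)]
        length = float(np.round(rng.uniform(lo, hi), 1))
        meta[r["id"]] = IndividualMeta(
            id=r["id"], sex=sex[r["id"]], total_length_cm=length,
            stage=stage_from_length(length), group="juvenile",
            site=r["nursery"], cohort_year=int(r["cohort_year"]),
        )

    sampled = ids + jids
    ped = pd.DataFrame(all_ped, columns=["id", "mother", "father", "cohort_year", "nursery"])
    truth = TruthSet(
        pedigree=ped,
        sex=sex,
        founders=founder_ids,
        genotypes_true=genotypes_true,
        true_freqs=freqs,
        sampled=sampled,
        meta=meta,
    )
    spec.null_allele_freqs = {l: q for l, q in zip(null_loci, (0.25, 0.20))}
    observed, obs_meta = apply_observation_model(truth, spec, rng)
    fixture = StudyFixture(
        table=observed,
        meta=obs_meta,
        truth=truth,
        null_loci=null_loci,
        outgroup=outgroup,
        breeders={
            "mothers_sampled": sampled_mothers,
            "fathers_sampled": sampled_fathers,
            "mothers_unsampled": unsampled_mothers,
            "fathers_unsampled": unsampled_fathers,
        },
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        gp = out_dir / "genotypes.gen"
        mp = out_dir / "metadata.csv"
        tp = out_dir / "truth.json"
        write_genotypes(observed, gp, format="genepop")
        write_metadata(obs_meta, mp)
        truth_doc = {
            "version": truth.version,
            "pedigree": ped.to_dict(orient="records"),
            "sampled": sampled,
            "null_loci": null_loci,
            "outgroup": outgroup,
            "breeders": fixture.breeders,
            "sex": sex,
        }
        tp.write_text(json.dumps(truth_doc, indent=1, sort_keys=True, default=str))
        fixture.paths = {"genotypes": gp, "metadata": mp, "truth": tp}
    return fixture
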