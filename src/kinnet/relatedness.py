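"""Maximum-likelihood pairwise relatedness and relationship classification.

A dyad's genotype data are scored under the Cotterman coefficients
(k0, k1, k2) — the probabilities of sharing 0, 1 or 2 alleles identical by
descent at a locus — with derived relatedness r = k1/2 + k2.  The ML
estimate searches the 2-simplex; the four classical pedigree relationships
are fixed points on it:

    U  = (1, 0, 0)        unrelated
    HS = (0.5, 0.5, 0)    half siblings (also avuncular / grandparental)
    FS = (0.25, 0.5, 0.25) full siblings
    PO = (0, 1, 0)        parent-offspring

Classification picks the category with the greatest multilocus likelihood;
an optional simulation-based significance test compares a null against an
alternative category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .genotypes import GenotypeTable
from .likelihood import LocusModel, build_locus_models, encode_table
from .qc import AlleleFrequencyTable, allele_frequencies, sequential_bonferroni

__all__ = [
    "CATEGORY_K",
    "FIRST_ORDER",
    "KCoefficients",
    "PairRelationship",
    "pair_locus_likelihood",
    "ml_k_estimate",
    "classify_relationship",
    "relationship_significance",
    "relatedness_matrix",
    "RelatednessResult",
    "mean_sd_offdiag",
    "significance_filter",
]

CATEGORY_K: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
}
#: Tie-break order: ties resolve toward the less-related category.
CATEGORY_ORDER = ("U", "HS", "FS", "PO")
FIRST_ORDER = ("PO", "FS", "HS")


@dataclass
class KCoefficients:
    """A point on the (k0, k1, k2) simplex."""

    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        for v in (self.k0, self.k1, self.k2):
            if v < -1e-9:
                raise ValueError("k coefficients must be non-negative")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("k coefficients must sum to 1")

    @property
    def r(self) -> float:
        """Relatedness coefficient r = k1/2 + k2."""
        return self.k1 / 2.0 + self.k2


@dataclass
class PairRelationship:
    id_a: str
    id_b: str
    ml_k: KCoefficients
    r_hat: float
    loglik: dict[str, float]
    ml_loglik: float
    best_category: str
    n_loci_used: int
    significance_p: float | None = None


# ---------------------------------------------------------------- likelihood


def pair_locus_likelihood(
    g1: Sequence[int],
    g2: Sequence[int],
    locus_freqs: Mapping[int, float],
    k: KCoefficients | tuple[float, float, float],
) -> float:
    """Probability of an unordered genotype pair at one locus given k.

    Returns ``k0*P0 + k1*P1 + k2*P2`` where P0 is the product of the two HWE
    genotype probabilities, P2 is P(g1) when the genotypes are identical
    (else 0), and P1 routes one allele of g2 through a uniformly chosen
    allele of g1 with the other an independent gene-pool draw.
    """
    if isinstance(k, KCoefficients):
        k0, k1, k2 = k.k0, k.k1, k.k2
    else:
        k0, k1, k2 = k
    g1 = tuple(sorted(int(a) for a in g1))
    g2 = tuple(sorted(int(a) for a in g2))
    for allele in (*g1, *g2):
        if allele not in locus_freqs:
            raise ValueError(f"allele {allele} absent from the frequency table")

    def p_hwe(g):
        a, b = g
        return locus_freqs[a] ** 2 if a == b else 2.0 * locus_freqs[a] * locus_freqs[b]

    def t1(child, parent):
        a, b = parent
        c, d = child
        total = 0.0
        for x in (a, b):
            if c == d:
                if x == c:
                    total += 0.5 * locus_freqs[c]
            else:
                if x == c:
                    total += 0.5 * locus_freqs[d]
                elif x == d:
                    total += 0.5 * locus_freqs[c]
        return total

    p0 = p_hwe(g1) * p_hwe(g2)
    p1 = p_hwe(g1) * t1(g2, g1)
    p2 = p_hwe(g1) if g1 == g2 else 0.0
    return k0 * p0 + k1 * p1 + k2 * p2


class PairScorer:
    """Precomputed per-locus (P0, P1, P2) tables for scoring dyads fast."""

    def __init__(
        self,
        table: GenotypeTable,
        freqs: AlleleFrequencyTable | None = None,
        individuals: Sequence[str] | None = None,
    ) -> None:
        if freqs is None:
            freqs = allele_frequencies(table)
        self.table = table
        self.freqs = freqs
        self.models = build_locus_models(freqs)
        self.loci = [l for l in table.loci if l in self.models]
        self.codes = encode_table(table, self.models)
        self._ind_index = {ind: i for i, ind in enumerate(table.individuals)}
        self._pair_tabs = {
            locus: self.models[locus].pair_tables() for locus in self.loci
        }

    def components(self, id_a: str, id_b: str) -> np.ndarray:
        """(3, n_shared_loci) array of (P0, P1, P2) for the dyad's typed loci."""
        ia, ib = self._ind_index[id_a], self._ind_index[id_b]
        ca, cb = self.codes[ia], self.codes[ib]
        shared = (ca >= 0) & (cb >= 0)
        if not shared.any():
            raise ValueError(f"dyad ({id_a}, {id_b}) shares no typed loci")
        cols = []
        for l in np.flatnonzero(shared):
            P0, P1, P2 = self._pair_tabs[self.loci[l]]
            g1, g2 = ca[l], cb[l]
            cols.append((P0[g1, g2], P1[g1, g2], P2[g1, g2]))
        return np.asarray(cols).T


_LATTICE: np.ndarray | None = None


def _simplex_lattice(step: float = 0.02) -> np.ndarray:
    global _LATTICE
    if _LATTICE is None:
        n = round(1.0 / step)
        pts = []
        for i in range(n + 1):
            for j in range(n + 1 - i):
                pts.append((i / n, j / n, (n - i - j) / n))
        _LATTICE = np.asarray(pts)
    return _LATTICE


def _loglik_of_k(k_vec: np.ndarray, comps: np.ndarray) -> np.ndarray:
    """Log-likelihood of one or many k vectors given (3, L) pair components."""
    mix = np.atleast_2d(k_vec) @ comps
    with np.errstate(divide="ignore"):
        return np.where(mix > 0, np.log(np.maximum(mix, 1e-300)), -np.inf).sum(axis=1)


def ml_k_estimate(
    comps_or_scorer,
    id_a: str | None = None,
    id_b: str | None = None,
) -> tuple[KCoefficients, float]:
    """Maximise the multilocus pair likelihood over the k simplex.

    Accepts either a precomputed (3, L) component array or a
    :class:`PairScorer` plus two IDs.  Deterministic: a fixed lattice
    (step 0.02) is scanned, then the best point is polished with SLSQP.
    """
    if isinstance(comps_or_scorer, PairScorer):
        comps = comps_or_scorer.components(id_a, id_b)
    else:
        comps = np.asarray(comps_or_scorer)
    lattice = _simplex_lattice()
    ll = _loglik_of_k(lattice, comps)
    best = int(np.argmax(ll))
    x0 = lattice[best, :2]  # free parameters (k0, k2); k1 = 1 - k0 - k2... see below

    # parametrise by (k0, k2)
    def neg_ll(x):
        k0, k2 = x
        k1 = 1.0 - k0 - k2
        if k0 < -1e-12 or k2 < -1e-12 or k1 < -1e-12:
            return 1e12
        k0, k2 = max(k0, 0.0), max(k2, 0.0)
        k1 = max(1.0 - k0 - k2, 0.0)
        ll = float(_loglik_of_k(np.array([k0, k1, k2]), comps)[0])
        return 1e12 if not np.isfinite(ll) else -ll

    x0 = np.array([lattice[best, 0], lattice[best, 2]])
    res = minimize(
        neg_ll,
        x0,
        method="SLSQP",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    cand = [(ll[best], lattice[best])]
    if res.success and np.isfinite(res.fun):
        k0, k2 = np.clip(res.x, 0.0, 1.0)
        k1 = max(0.0, 1.0 - k0 - k2)
        s = k0 + k1 + k2
        vec = np.array([k0 / s, k1 / s, k2 / s])
        cand.append((float(_loglik_of_k(vec, comps)[0]), vec))
    best_ll, best_vec = max(cand, key=lambda t: t[0])
    return KCoefficients(*[float(v) for v in best_vec]), float(best_ll)


def classify_relationship(
    scorer: PairScorer,
    id_a: str,
    id_b: str,
    significance: bool = False,
    n_sim: int = 5000,
    seed: int | None = None,
) -> PairRelationship:
    """ML k estimate plus the best of the four fixed pedigree hypotheses.

    Ties in the category likelihoods break toward the less-related category
    in the order U > HS > FS > PO.
    """
    comps = scorer.components(id_a, id_b)
    ml_k, ml_ll = ml_k_estimate(comps)
    logliks = {
        cat: float(_loglik_of_k(np.asarray(CATEGORY_K[cat]), comps)[0])
        for cat in CATEGORY_ORDER
    }
    best_cat = max(CATEGORY_ORDER, key=lambda c: (logliks[c], -CATEGORY_ORDER.index(c)))
    # explicit tie-break toward less related: first category within 1e-12 of max
    top = logliks[best_cat]
    for cat in CATEGORY_ORDER:
        if logliks[cat] >= top - 1e-12:
            best_cat = cat
            break
    rel = PairRelationship(
        id_a=id_a,
        id_b=id_b,
        ml_k=ml_k,
        r_hat=ml_k.r,
        loglik=logliks,
        ml_loglik=ml_ll,
        best_category=best_cat,
        n_loci_used=comps.shape[1],
    )
    if significance and best_cat != "U":
        rel.significance_p = relationship_significance(
            scorer, id_a, id_b, "U", best_cat, n_sim=n_sim, seed=seed
        )
    return rel


# ------------------------------------------------------- significance testing


def _category_loglik_tables(model: LocusModel) -> dict[str, np.ndarray]:
    P0, P1, P2 = model.pair_tables()
    out = {}
    for cat, (k0, k1, k2) in CATEGORY_K.items():
        mix = k0 * P0 + k1 * P1 + k2 * P2
        with np.errstate(divide="ignore"):
            out[cat] = np.log(mix)
    return out


def _simulate_pairs_category(
    model: LocusModel, k: tuple[float, float, float], n: int, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n genotype-pair codes at one locus for a dyad related by k."""
    G = model.n_genotypes
    state = rng.choice(3, size=n, p=list(k))
    g1 = rng.choice(G, size=n, p=model.gp)
    g2 = np.empty(n, dtype=np.int64)
    m0 = state == 0
    g2[m0] = rng.choice(G, size=int(m0.sum()), p=model.gp)
    m2 = state == 2
    g2[m2] = g1[m2]
    m1 = state == 1
    n1 = int(m1.sum())
    if n1:
        s = rng.choice(model.n_alleles, size=n1, p=model.p)
        u = rng.choice(model.n_alleles, size=n1, p=model.p)
        v = rng.choice(model.n_alleles, size=n1, p=model.p)
        g1[m1] = model.gcode[s, u]
        g2[m1] = model.gcode[s, v]
    return g1, g2


def relationship_significance(
    scorer: PairScorer,
    id_a: str,
    id_b: str,
    null_category: str = "U",
    alt_category: str = "FS",
    n_sim: int = 5000,
    seed: int | None = None,
) -> float:
    """Simulation p-value for preferring ``alt_category`` over ``null_category``.

    Pairs are simulated under the null category over the dyad's typed loci;
    p is the add-one-rule proportion of simulated log-likelihood ratios
    (alt minus null) at least as large as the observed one.
    """
    if null_category == alt_category:
        raise ValueError("null and alternative categories must differ")
    rng = np.random.default_rng(seed)
    ia = scorer._ind_index[id_a]
    ib = scorer._ind_index[id_b]
    ca, cb = scorer.codes[ia], scorer.codes[ib]
    shared = np.flatnonzero((ca >= 0) & (cb >= 0))
    if shared.size == 0:
        raise ValueError("no shared typed loci")
    k_null = CATEGORY_K[null_category]
    obs = 0.0
    llr_sim = np.zeros(n_sim)
    for l in shared:
        model = scorer.models[scorer.loci[l]]
        tabs = _category_loglik_tables(model)
        delta = tabs[alt_category] - tabs[null_category]
        obs += float(delta[ca[l], cb[l]])
        g1, g2 = _simulate_pairs_category(model, k_null, n_sim, rng)
        llr_sim += delta[g1, g2]
    b = int(np.sum(llr_sim >= obs - 1e-12))
    return (b + 1) / (n_sim + 1)


def significance_filter(
    scorer: PairScorer,
    dyads: pd.DataFrame,
    alpha: float = 0.05,
    n_null: int = 200_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Family-wise significance screen of first-order dyad calls.

    For every dyad whose best category is first-order, the observed
    log-likelihood ratio (best category vs U) is compared against a pooled
    null built from ``n_null`` simulated unrelated pairs; per-locus null
    samples are stored so each dyad's null conditions on its own typed-locus
    pattern.  Holm correction across tested dyads controls the family-wise
    error at ``alpha``.  Returns a copy of ``dyads`` with ``significance_p``
    and ``significant`` columns.
    """
    rng = np.random.default_rng(seed)
    loci = scorer.loci
    null_per_locus: dict[str, np.ndarray] = {}
    delta_tabs: dict[str, dict[str, np.ndarray]] = {}
    for locus in loci:
        model = scorer.models[locus]
        tabs = _category_loglik_tables(model)
        delta_tabs[locus] = {
            cat: tabs[cat] - tabs["U"] for cat in FIRST_ORDER
        }
        g1, g2 = _simulate_pairs_category(model, CATEGORY_K["U"], n_null, rng)
        null_per_locus[locus] = np.stack(
            [delta_tabs[locus][cat][g1, g2] for cat in FIRST_ORDER]
        ).astype(np.float32)  # (3, n_null)
    cat_idx = {cat: i for i, cat in enumerate(FIRST_ORDER)}
    out = dyads.copy()
    out["significance_p"] = np.nan
    tested = []
    pvals = []
    for row in out.itertuples():
        if row.best_category not in cat_idx:
            continue
        ia = scorer._ind_index[row.id_a]
        ib = scorer._ind_index[row.id_b]
        ca, cb = scorer.codes[ia], scorer.codes[ib]
        shared = np.flatnonzero((ca >= 0) & (cb >= 0))
        ci = cat_idx[row.best_category]
        obs = 0.0
        null = np.zeros(n_null, dtype=np.float64)
        for l in shared:
            locus = loci[l]
            obs += float(delta_tabs[locus][row.best_category][ca[l], cb[l]])
            null += null_per_locus[locus][ci]
        p = (int(np.sum(null >= obs - 1e-9)) + 1) / (n_null + 1)
        tested.append(row.Index)
        pvals.append(p)
    out["significant"] = False
    if tested:
        holm = sequential_bonferroni(pvals, alpha)
        out.loc[tested, "significance_p"] = pvals
        out.loc[tested, "significant"] = holm.reject
    return out


# ------------------------------------------------------------------- matrices


@dataclass
class RelatednessResult:
    """Pairwise ML relatedness over a set of individuals."""

    ids: list[str]
    r: pd.DataFrame
    category: pd.DataFrame
    dyads: pd.DataFrame
    pairs: list[PairRelationship] = field(repr=False, default_factory=list)


def relatedness_matrix(
    table: GenotypeTable,
    freqs: AlleleFrequencyTable | None = None,
    ids: Sequence[str] | None = None,
) -> RelatednessResult:
    """Symmetric r-hat and best-category matrices over all dyads of ``ids``.

    Frequencies default to all genotyped individuals in ``table`` (they may
    be a superset of ``ids``).  The diagonal is NaN / empty.
    """
    if ids is None:
        ids = list(table.individuals)
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("need at least two individuals")
    scorer = PairScorer(table, freqs)
    n = len(ids)
    r = np.full((n, n), np.nan)
    cat = np.full((n, n), "", dtype=object)
    pairs = []
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            rel = classify_relationship(scorer, ids[i], ids[j])
            r[i, j] = r[j, i] = rel.r_hat
            cat[i, j] = cat[j, i] = rel.best_category
            pairs.append(rel)
            rows.append(
                {
                    "id_a": ids[i],
                    "id_b": ids[j],
                    "r_hat": rel.r_hat,
                    "k0": rel.ml_k.k0,
                    "k1": rel.ml_k.k1,
                    "k2": rel.ml_k.k2,
                    "best_category": rel.best_category,
                    "loglik_U": rel.loglik["U"],
                    "loglik_HS": rel.loglik["HS"],
                    "loglik_FS": rel.loglik["FS"],
                    "loglik_PO": rel.loglik["PO"],
                    "n_loci": rel.n_loci_used,
                }
            )
    return RelatednessResult(
        ids=ids,
        r=pd.DataFrame(r, index=ids, columns=ids),
        category=pd.DataFrame(cat, index=ids, columns=ids),
        dyads=pd.DataFrame(rows),
        pairs=pairs,
    )


def mean_sd_offdiag(r: pd.DataFrame) -> tuple[float, float]:
    """Mean and SD of r-hat over the off-diagonal dyads (each counted once)."""
    vals = r.to_numpy()
    iu = np.triu_indices(vals.shape[0], k=1)
    v = vals[iu]
    v = v[~np.isnan(v)]
    return float(np.mean(v)), float(np.std(v, ddof=1))
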