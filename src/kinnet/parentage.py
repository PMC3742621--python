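"""Likelihood-based parentage assignment and sibship reconstruction.

Two layers mirror the classic two-program workflow for wild pedigrees:

1. *Assignment*: each offspring is scored against every candidate parent of
   each sex with a LOD score — the log ratio of the likelihood that the
   candidate is a parent (co-parent drawn from the gene pool) to the
   likelihood that both parents are random gene-pool draws — under a simple
   genotyping-error model (with probability *e* per individual per locus the
   observed genotype is an independent HWE draw).  Confidence thresholds on
   Delta (best minus second-best LOD) are calibrated by simulation so that a
   stated fraction of assignments made above the threshold are correct.
2. *Sibship*: offspring are partitioned into maternal and paternal families
   (polygamy allowed for both sexes), each family headed by a sampled
   candidate or a latent parent.  A simulated-annealing search maximises the
   full configuration likelihood: latent heads' multilocus genotypes are
   marginalised exactly over the bipartite mother x father family graph
   (cyclic components on a maximum-evidence spanning tree), with prior
   terms for sampled heads and a finite-pool prior on the number of
   families per sex.  Known mother/offspring and father/offspring pairs
   from the assignment layer are hard constraints.

Latent parents are labelled ``#k`` (mothers) and ``*k`` (fathers).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeTable, IndividualMeta
from .likelihood import LocusModel, build_locus_models, encode_table
from .qc import AlleleFrequencyTable

__all__ = [
    "ParentageAssignment",
    "SibshipSolution",
    "SibshipResult",
    "BreederCount",
    "Litter",
    "LitterSummary",
    "ParentageScorer",
    "mendelian_mismatches",
    "parent_lod",
    "delta_criticals",
    "assign_parents",
    "sibship_reconstruct",
    "exhaustive_sibship",
    "reconstruct_parent_genotypes",
    "count_breeders",
    "litter_table",
]


# --------------------------------------------------------------- exclusions


def mendelian_mismatches(offspring: np.ndarray, candidate: np.ndarray) -> int:
    """Count loci where the candidate shares no allele with the offspring.

    Both arguments are (n_loci, 2) call arrays; loci missing in either are
    excluded.  Requires at least one shared typed locus.
    """
    offspring = np.asarray(offspring)
    candidate = np.asarray(candidate)
    shared = (offspring[:, 0] != MISSING) & (candidate[:, 0] != MISSING)
    if not shared.any():
        raise ValueError("no shared typed loci")
    o, c = offspring[shared], candidate[shared]
    share = (
        (o[:, 0:1] == c[:, 0:1])
        | (o[:, 0:1] == c[:, 1:2])
        | (o[:, 1:2] == c[:, 0:1])
        | (o[:, 1:2] == c[:, 1:2])
    ).any(axis=1)
    return int(np.sum(~share))


# ------------------------------------------------------------------- scorer


class ParentageScorer:
    """Precomputed LOD and family-likelihood tables for one dataset.

    Parameters
    ----------
    table, freqs
        Genotypes and the allele-frequency table used for all likelihoods.
    error_rate
        Per-individual per-locus probability that the observed genotype is
        an independent HWE draw.
    """

    def __init__(
        self,
        table: GenotypeTable,
        freqs: AlleleFrequencyTable,
        error_rate: float = 0.01,
    ) -> None:
        self.table = table
        self.freqs = freqs
        self.e = float(error_rate)
        self.models = build_locus_models(freqs)
        self.loci = [l for l in table.loci if l in self.models]
        self.codes = encode_table(table, self.models)
        self.ind_index = {ind: i for i, ind in enumerate(table.individuals)}
        e = self.e
        keep2 = (1.0 - e) ** 2
        self.lod_tabs: dict[str, np.ndarray] = {}
        self.fam_tabs: dict[str, np.ndarray] = {}
        for locus in self.loci:
            m = self.models[locus]
            with np.errstate(divide="ignore"):
                self.lod_tabs[locus] = np.log(
                    keep2 * m.T1 / m.gp[None, :] + (1.0 - keep2)
                )
            self.fam_tabs[locus] = (1.0 - e) * m.T1 + e * m.gp[None, :]
        # padded stacks for vectorised family likelihoods
        L = len(self.loci)
        self.Gmax = max(self.models[l].n_genotypes for l in self.loci) if L else 0
        self.FT = np.ones((L, self.Gmax, self.Gmax))
        self.GPpad = np.zeros((L, self.Gmax))
        self.TR: dict[str, np.ndarray] = {}  # per locus (G, k) transmission probs
        for l, locus in enumerate(self.loci):
            m = self.models[locus]
            G = m.n_genotypes
            self.FT[l, :G, :G] = self.fam_tabs[locus]
            self.FT[l, G:, :] = 0.0
            self.GPpad[l, :G] = m.gp
            tr = np.zeros((G, m.n_alleles))
            for g, (a, b) in enumerate(m.genotypes):
                tr[g, a] += 0.5
                tr[g, b] += 0.5
            self.TR[locus] = tr
        self._w_cache: dict[str | None, np.ndarray] = {}
        self._phi_cache: dict[int, np.ndarray] = {}

    def parent_weights(self, parent: str | None) -> np.ndarray:
        """(L, Gmax) distribution over a family head's true genotype per locus:
        the HWE prior for a latent parent; for a sampled parent, its observed
        genotype with probability 1-e, otherwise an HWE draw."""
        if parent in self._w_cache:
            return self._w_cache[parent]
        if parent is None:
            w = self.GPpad
        else:
            row = self.ind_index[parent]
            w = self.e * self.GPpad.copy()
            for l in range(len(self.loci)):
                g = self.codes[row, l]
                if g < 0:
                    w[l] = self.GPpad[l]
                else:
                    w[l, g] += 1.0 - self.e
        self._w_cache[parent] = w
        return w

    def family_loglik(
        self,
        offspring_rows: np.ndarray,
        parent: str | None,
        off_factors: np.ndarray | None = None,
    ) -> float:
        """Log marginal likelihood of one family sharing a single parent.

        The shared parent's genotype is summed out per locus against
        ``parent_weights``; each offspring's co-parent is an independent
        gene-pool draw and observation error is folded into the
        per-offspring transmission factor.  ``off_factors`` optionally
        supplies custom per-offspring (L, Gmax) factors over the shared
        parent's genotype in place of the gene-pool default.
        """
        rows = np.asarray(offspring_rows)
        if rows.size == 0:
            return 0.0
        if off_factors is not None:
            T = off_factors[rows]  # (m, L, Gmax)
        else:
            C = self.codes[rows]  # (m, L)
            valid = C >= 0
            Cs = np.where(valid, C, 0)
            lgrid = np.broadcast_to(np.arange(len(self.loci)), Cs.shape)
            T = self.FT[lgrid, :, Cs]  # (m, L, Gmax)
            T[~valid] = 1.0
        per_locus = (self.parent_weights(parent) * T.prod(axis=0)).sum(axis=1)
        return float(np.log(per_locus + 1e-300).sum())

    def off_phi(self, row: int) -> np.ndarray:
        """(L, Gmax, Gmax) per-locus factors P(offspring obs | mother gm,
        father gf) under the error mixture; all-ones rows where the
        offspring is untyped.  Cached per individual row."""
        cached = self._phi_cache.get(int(row))
        if cached is not None:
            return cached
        L = len(self.loci)
        out = np.ones((L, self.Gmax, self.Gmax), dtype=np.float32)
        e = self.e
        for l, locus in enumerate(self.loci):
            m = self.models[locus]
            go = self.codes[row, l]
            if go < 0:
                continue
            G = m.n_genotypes
            tr = self.TR[locus]
            a, b = m.genotypes[go]
            if a == b:
                M = np.outer(tr[:, a], tr[:, a])
            else:
                M = np.outer(tr[:, a], tr[:, b]) + np.outer(tr[:, b], tr[:, a])
            out[l, :, :] = e * m.gp[go]
            out[l, :G, :G] = (1.0 - e) * M + e * m.gp[go]
        self._phi_cache[int(row)] = out
        return out

    def lod_pair(self, offspring_id: str, candidate_id: str) -> float:
        io = self.ind_index[offspring_id]
        ic = self.ind_index[candidate_id]
        total = 0.0
        used = 0
        for l, locus in enumerate(self.loci):
            go, gc = self.codes[io, l], self.codes[ic, l]
            if go < 0 or gc < 0:
                continue
            total += float(self.lod_tabs[locus][gc, go])
            used += 1
        if used == 0:
            raise ValueError("no shared typed loci")
        return total

    def lod_matrix(
        self, offspring_ids: Sequence[str], candidate_ids: Sequence[str]
    ) -> np.ndarray:
        """(n_offspring, n_candidates) total LOD scores."""
        io = np.array([self.ind_index[i] for i in offspring_ids])
        ic = np.array([self.ind_index[i] for i in candidate_ids])
        out = np.zeros((len(io), len(ic)))
        for l, locus in enumerate(self.loci):
            go = self.codes[io, l]
            gc = self.codes[ic, l]
            ok = (go[:, None] >= 0) & (gc[None, :] >= 0)
            vals = self.lod_tabs[locus][gc[None, :], go[:, None]]
            out += np.where(ok, vals, 0.0)
        return out


def parent_lod(
    offspring: np.ndarray,
    candidate: np.ndarray,
    freqs: AlleleFrequencyTable,
    error_rate: float = 0.01,
) -> float:
    """Total parent-offspring LOD for two (n_loci, 2) call arrays.

    Additive over loci; with ``error_rate`` 0 a Mendelian mismatch makes the
    LOD −inf (hard exclusion).
    """
    loci = freqs.loci()
    t = GenotypeTable(
        ["off", "cand"], loci, np.stack([np.asarray(offspring), np.asarray(candidate)])
    )
    scorer = ParentageScorer(t, freqs, error_rate)
    return scorer.lod_pair("off", "cand")


# ---------------------------------------------------------------- criticals


def _sample_codes(model: LocusModel, shape, rng) -> np.ndarray:
    return rng.choice(model.n_genotypes, size=shape, p=model.gp)


def delta_criticals(
    freqs: AlleleFrequencyTable,
    n_candidates: int,
    prop_parents_sampled: float,
    confidence: float = 0.95,
    n_sim: int = 10_000,
    error_rate: float = 0.01,
    seed: int | None = None,
) -> float:
    """Simulate the Delta threshold achieving the requested assignment confidence.

    Offspring are simulated with their true parent present among the
    ``n_candidates`` with probability ``prop_parents_sampled``; Delta is the
    gap between the best and second-best candidate LOD.  The returned
    critical value is the smallest threshold at which at least ``confidence``
    of the assignments made above it are correct (0 when even unthresholded
    assignment meets the confidence).
    """
    if not (0.0 < prop_parents_sampled <= 1.0):
        raise ValueError("prop_parents_sampled must be in (0, 1]")
    rng = np.random.default_rng(seed)
    tmp = GenotypeTable(
        ["x"], freqs.loci(), np.full((1, len(freqs.loci()), 2), MISSING)
    )
    scorer = ParentageScorer(tmp, freqs, error_rate)
    e = scorer.e
    sampled = rng.random(n_sim) < prop_parents_sampled
    lods = np.zeros((n_sim, n_candidates))
    for locus in scorer.loci:
        m = scorer.models[locus]
        cand = _sample_codes(m, (n_sim, n_candidates), rng)
        true_parent = np.where(sampled, cand[:, 0], _sample_codes(m, n_sim, rng))
        # offspring: one allele from the true parent, co-parent from the pool
        cum = np.cumsum(m.T1, axis=1)
        u = rng.random(n_sim)
        child = (cum[true_parent] < u[:, None]).sum(axis=1)
        err = rng.random(n_sim) < e
        child[err] = _sample_codes(m, int(err.sum()), rng)
        # observation error on the true parent's genotype when it is sampled
        obs_err = (rng.random(n_sim) < e) & sampled
        cand[obs_err, 0] = _sample_codes(m, int(obs_err.sum()), rng)
        lods += scorer.lod_tabs[locus][cand, child[:, None]]
    order = np.argsort(lods, axis=1)
    best = order[:, -1]
    lod_best = lods[np.arange(n_sim), best]
    delta = lod_best - lods[np.arange(n_sim), order[:, -2]]
    correct = sampled & (best == 0)
    if not correct.any():
        raise RuntimeError(
            "no correct assignments in the Delta simulation; increase n_sim"
        )
    # an assignment is only ever made to a positive-LOD best candidate;
    # scan prefixes of those sims sorted by decreasing Delta for the largest
    # assignment set whose precision still meets the confidence level
    made = lod_best > 0
    delta_m, correct_m = delta[made], correct[made]
    n_made = int(made.sum())
    idx = np.argsort(-delta_m, kind="stable")
    precision = np.cumsum(correct_m[idx]) / np.arange(1, n_made + 1)
    ok = np.flatnonzero(precision >= confidence)
    if ok.size == 0:
        raise RuntimeError("confidence level unreachable in simulation")
    m_best = int(ok[-1])
    if m_best == n_made - 1:
        return 0.0
    return float(max(delta_m[idx][m_best], 0.0))


# --------------------------------------------------------------- assignment


@dataclass
class ParentageAssignment:
    offspring_id: str
    mother_ref: str | None = None
    father_ref: str | None = None
    lod_mother: float | None = None
    lod_father: float | None = None
    delta_mother: float | None = None
    delta_father: float | None = None
    confidence_mother: str = "unassigned"
    confidence_father: str = "unassigned"

    @property
    def outcome(self) -> str:
        """'pair', 'mother_only', 'father_only' or 'unassigned'."""
        m = self.confidence_mother == "strict95"
        f = self.confidence_father == "strict95"
        if m and f:
            return "pair"
        if m:
            return "mother_only"
        if f:
            return "father_only"
        return "unassigned"


def assign_parents(
    scorer: ParentageScorer,
    offspring_ids: Sequence[str],
    candidate_mothers: Sequence[str],
    candidate_fathers: Sequence[str],
    criticals: Mapping[str, float],
) -> list[ParentageAssignment]:
    """Strict-confidence parent assignment per offspring and per sex.

    ``criticals`` maps 'mother'/'father' to the simulated Delta thresholds.
    A parent is assigned at strict95 when its LOD is positive, it is the
    best candidate of its sex, and Delta >= the critical value.  Mother-only,
    father-only and pair outcomes all occur naturally.
    """
    out = [ParentageAssignment(o) for o in offspring_ids]
    for sex, cands in (("mother", candidate_mothers), ("father", candidate_fathers)):
        if not cands:
            continue
        lods = scorer.lod_matrix(offspring_ids, cands)
        crit = float(criticals[sex])
        for i, a in enumerate(out):
            row = lods[i]
            order = np.argsort(row)
            best = int(order[-1])
            lod_best = float(row[best])
            delta = float(lod_best - row[order[-2]]) if len(cands) > 1 else math.inf
            ref = cands[best]
            assigned = lod_best > 0 and delta >= crit
            if sex == "mother":
                a.lod_mother, a.delta_mother = lod_best, delta
                if assigned:
                    a.mother_ref, a.confidence_mother = ref, "strict95"
            else:
                a.lod_father, a.delta_father = lod_best, delta
                if assigned:
                    a.father_ref, a.confidence_father = ref, "strict95"
    return out


# ------------------------------------------------------------------ sibship


@dataclass
class SibshipSolution:
    """One best configuration: maternal and paternal partitions with parents."""

    offspring: list[str]
    maternal_families: dict[str, list[str]]  # parent ref -> offspring ids
    paternal_families: dict[str, list[str]]
    loglik: float
    seed: int | None = None
    replicate: int = 0

    def family_of(self, side: str, offspring_id: str) -> str:
        fams = self.maternal_families if side == "mother" else self.paternal_families
        for ref, members in fams.items():
            if offspring_id in members:
                return ref
        raise KeyError(offspring_id)


@dataclass
class SibshipResult:
    best: SibshipSolution
    replicates: list[SibshipSolution]
    pairwise_agreement: float


def _known_from_assignments(
    assignments: Sequence[ParentageAssignment] | None, sex: str
) -> dict[str, str]:
    known = {}
    if assignments:
        for a in assignments:
            ref = a.mother_ref if sex == "mother" else a.father_ref
            conf = a.confidence_mother if sex == "mother" else a.confidence_father
            if ref is not None and conf == "strict95":
                known[a.offspring_id] = ref
    return known




def _partition_prior(k: int, pool: int) -> float:
    """Log prior of k distinct families when each offspring's parent is a
    uniform draw from a pool of ``pool`` parents (falling factorial,
    softened beyond the pool so transient search states stay finite)."""
    terms = np.clip(pool - np.arange(k, dtype=float), 0.25, None)
    return float(np.sum(np.log(terms)))


class _JointSibshipState:
    """Joint maternal x paternal sibship configuration with exact scoring.

    The configuration likelihood marginalises every family head's multilocus
    genotype exactly: families of the two sexes form a bipartite graph whose
    edges carry, per locus, the product of the member offsprings' Mendelian
    transmission factors (with the genotyping-error mixture); acyclic
    components are eliminated leaf-to-root with per-locus rescaling, and the
    rare cyclic components fall back to generic per-locus variable
    elimination.  Priors: a sampled family head carries
    log(p/(1-p)) - log(n_candidates); the number of families per side
    follows the finite-pool falling-factorial prior.
    """

    SIDES = ("M", "F")

    def __init__(self, scorer, offspring_ids, candidates, prior_sampled,
                 locked, pools):
        self.sc = scorer
        self.offspring = list(offspring_ids)
        self.rows = np.array(
            [scorer.ind_index[o] for o in self.offspring], dtype=np.int64
        )
        self.n = len(self.offspring)
        self.cand = candidates
        self.bonus: dict[str, float] = {}
        self._prior_cum: dict[str, np.ndarray] = {}
        self.pool: dict[str, int] = {}
        self.fams: dict[str, dict[int, dict]] = {s: {} for s in self.SIDES}
        self.assign: dict[str, dict[int, int]] = {s: {} for s in self.SIDES}
        self.locked: dict[str, dict[int, int]] = {s: {} for s in self.SIDES}
        self.free: dict[str, list[str]] = {}
        self._next = {s: 0 for s in self.SIDES}
        self._cache: dict[frozenset, float] = {}
        for s in self.SIDES:
            n_cand = max(len(candidates[s]), 1)
            p = prior_sampled[s]
            self.bonus[s] = (
                math.log(p) - math.log(max(1.0 - p, 1e-12)) - math.log(n_cand)
            )
            ps = pools[s]
            if ps is None:
                ps = len(candidates[s]) + self.n
            self.pool[s] = max(int(ps), 1)
            kmax = self.n + n_cand + 1
            terms = np.log(
                np.clip(self.pool[s] - np.arange(kmax, dtype=float), 0.25, None)
            )
            self._prior_cum[s] = np.concatenate([[0.0], np.cumsum(terms)])
            by_parent: dict[str, list[int]] = {}
            for pos, o in enumerate(self.offspring):
                par = locked[s].get(o)
                if par is not None:
                    by_parent.setdefault(par, []).append(pos)
            used = set()
            for parent, members in by_parent.items():
                fid = self._new_fam(s, set(members), parent)
                used.add(parent)
                for pos in members:
                    self.locked[s][pos] = fid
            for pos in range(self.n):
                if pos not in self.locked[s]:
                    self._new_fam(s, {pos}, None)
            self.free[s] = [c for c in candidates[s] if c not in used]
        # multi-offspring edge potentials, keyed (mfid, ffid) and validated
        # against the member signature (singleton edges reuse phi directly)
        self._edge_cache: dict[tuple[int, int], tuple[frozenset, np.ndarray]] = {}
        self.score = self.total_score()

    # ------------------------------------------------------------ families
    def _new_fam(self, side, members, parent) -> int:
        fid = self._next[side]
        self._next[side] += 1
        self.fams[side][fid] = {"members": members, "parent": parent}
        for pos in members:
            self.assign[side][pos] = fid
        return fid

    def _drop_empty(self, side, fid) -> None:
        fam = self.fams[side].get(fid)
        if fam is not None and not fam["members"]:
            if fam["parent"] is not None:
                self.free[side].append(fam["parent"])
            del self.fams[side][fid]

    def _k(self, side) -> int:
        return sum(1 for f in self.fams[side].values() if f["members"])

    def prior_term(self, side, k) -> float:
        arr = self._prior_cum[side]
        return float(arr[min(k, len(arr) - 1)])

    def _prior_total(self) -> float:
        total = 0.0
        for s in self.SIDES:
            fams = [f for f in self.fams[s].values() if f["members"]]
            total += self.prior_term(s, len(fams))
            total += sum(self.bonus[s] for f in fams if f["parent"] is not None)
        return total

    # --------------------------------------------------------------- graph
    def _neighbors(self, node):
        side, fid = node
        other = "F" if side == "M" else "M"
        return {
            (other, self.assign[other][pos])
            for pos in self.fams[side][fid]["members"]
        }

    def _live(self, node) -> bool:
        side, fid = node
        fam = self.fams[side].get(fid)
        return fam is not None and bool(fam["members"])

    def _comps_containing(self, nodes) -> list[frozenset]:
        remaining = {n for n in nodes if self._live(n)}
        comps = []
        while remaining:
            start = remaining.pop()
            seen = {start}
            stack = [start]
            while stack:
                cur = stack.pop()
                for nb in self._neighbors(cur):
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            comps.append(frozenset(seen))
            remaining -= seen
        return comps

    def all_nodes(self):
        return [
            (s, fid)
            for s in self.SIDES
            for fid, f in self.fams[s].items()
            if f["members"]
        ]

    # ---------------------------------------------------------- likelihood
    def _edge_pot(self, mfid, ffid, positions) -> np.ndarray:
        sc = self.sc
        if len(positions) == 1:
            return sc.off_phi(self.rows[positions[0]])  # shared, do not mutate
        cache = getattr(self, "_edge_cache", None)
        if cache is None:
            cache = self._edge_cache = {}
        key = (mfid, ffid)
        sig = frozenset(positions)
        cached = cache.get(key)
        if cached is not None and cached[0] == sig:
            return cached[1]
        pot = sc.off_phi(self.rows[positions[0]]).copy()
        for pos in positions[1:]:
            pot *= sc.off_phi(self.rows[pos])
        cache[key] = (sig, pot)
        if len(cache) > 512:
            cache.pop(next(iter(cache)))
        return pot

    def _comp_tree(self, nodes):
        """Spanning-tree factorisation of one family-graph component.

        Edges (matings) are ranked by offspring count and a maximum-evidence
        spanning tree is kept exactly; each cut mating's joint offspring
        factor phi(gm, gf) is replaced by A(gm) * B(gf) / P(go) — the
        rank-1 approximation that preserves both single-parent marginals —
        folded into the two parents' priors plus a constant.  Returns
        (priors, adj, pots, logconst).
        """
        sc = self.sc
        priors = {}
        edge_members: dict[tuple, list[int]] = {}
        for node in nodes:
            side, fid = node
            fam = self.fams[side][fid]
            priors[node] = sc.parent_weights(fam["parent"])
            if side != "M":
                continue
            for pos in fam["members"]:
                fnode = ("F", self.assign["F"][pos])
                edge_members.setdefault((node, fnode), []).append(pos)
        uf = {n: n for n in nodes}

        def find(x):
            while uf[x] != x:
                uf[x] = uf[uf[x]]
                x = uf[x]
            return x

        tree_edges, cut_edges = [], []
        for key in sorted(edge_members, key=lambda k: (-len(edge_members[k]), k)):
            ra, rb = find(key[0]), find(key[1])
            if ra == rb:
                cut_edges.append(key)
            else:
                uf[ra] = rb
                tree_edges.append(key)
        pots = {}
        adj: dict[tuple, set] = {n: set() for n in nodes}
        for mn, fn in tree_edges:
            pots[(mn, fn)] = self._edge_pot(mn[1], fn[1], edge_members[(mn, fn)])
            adj[mn].add(fn)
            adj[fn].add(mn)
        logconst = 0.0
        for mn, fn in cut_edges:
            for pos in edge_members[(mn, fn)]:
                C = sc.codes[self.rows[pos]]
                valid = C >= 0
                Cs = np.where(valid, C, 0)
                col = sc.FT[np.arange(len(sc.loci)), :, Cs]  # (L, Gmax)
                col[~valid] = 1.0
                priors[mn] = priors[mn] * col
                priors[fn] = priors[fn] * col
                for l in np.flatnonzero(valid):
                    logconst -= math.log(
                        sc.models[sc.loci[l]].gp[C[l]]
                    )
        return priors, adj, pots, logconst

    def _eval_fresh(self, nodes) -> float:
        priors, adj, pots, logscale = self._comp_tree(nodes)
        active = set(nodes)
        while len(active) > 1:
            leaf = None
            for n2 in active:
                if len(adj[n2]) <= 1:
                    leaf = n2
                    break
            if not adj[leaf]:
                tot = priors[leaf].sum(axis=1)
                logscale += float(np.log(np.maximum(tot, 1e-300)).sum())
                active.discard(leaf)
                continue
            (other,) = adj[leaf]
            if leaf[0] == "M":
                msg = np.einsum("lg,lgh->lh", priors[leaf], pots[(leaf, other)])
            else:
                msg = np.einsum("lh,lgh->lg", priors[leaf], pots[(other, leaf)])
            pr = priors[other] * msg
            m = pr.max(axis=1)
            m[m <= 0] = 1.0
            logscale += float(np.log(m).sum())
            priors = {**priors, other: pr / m[:, None]}
            active.discard(leaf)
            adj[other].discard(leaf)
        last = active.pop()
        tot = priors[last].sum(axis=1)
        return float(np.log(np.maximum(tot, 1e-300)).sum()) + logscale

    def _affected_eval(self, touched_nodes, use_cache=True):
        comps = self._comps_containing(touched_nodes)
        vals = []
        for comp in comps:
            if use_cache and comp in self._cache:
                vals.append((comp, self._cache[comp]))
            else:
                vals.append((comp, self._eval_fresh(comp)))
        return comps, vals

    def total_score(self) -> float:
        comps = self._comps_containing(self.all_nodes())
        self._cache = {c: self._eval_fresh(c) for c in comps}
        return sum(self._cache.values()) + self._prior_total()

    # ----------------------------------------------------------------- moves
    def _finalize(self, before_comps, before_vals, touched_after, k_args,
                  undo_members, commit_extra=None, extra_delta=0.0):
        after_comps, after_vals = self._affected_eval(touched_after,
                                                      use_cache=False)
        delta = sum(v for _, v in after_vals) - sum(v for _, v in before_vals)
        delta += extra_delta
        for side, k_a, k_b in k_args:
            delta += self.prior_term(side, k_a) - self.prior_term(side, k_b)

        def commit():
            for c in before_comps:
                self._cache.pop(c, None)
            for c, v in after_vals:
                self._cache[c] = v
            if commit_extra:
                commit_extra()

        return delta, undo_members, commit

    def move_offspring(self, rng):
        side = self.SIDES[rng.integers(2)]
        movable = [p for p in range(self.n) if p not in self.locked[side]]
        if not movable:
            return None
        pos = movable[int(rng.integers(len(movable)))]
        src = self.assign[side][pos]
        others = [fid for fid in self.fams[side] if fid != src]
        choice = int(rng.integers(len(others) + 1))
        new_fam = choice == len(others)
        touched = {(side, src)} | (set() if new_fam else {(side, others[choice])})
        before_comps, before_vals = self._affected_eval(touched)
        k_b = self._k(side)
        dst = self._new_fam(side, set(), None) if new_fam else others[choice]
        self.fams[side][src]["members"].discard(pos)
        self.fams[side][dst]["members"].add(pos)
        self.assign[side][pos] = dst
        src_empty = not self.fams[side][src]["members"]
        k_a = k_b + (1 if new_fam else 0) - (1 if src_empty else 0)
        bonus_delta = (
            -self.bonus[side]
            if src_empty and self.fams[side][src]["parent"] is not None
            else 0.0
        )
        after_nodes = set().union(*map(set, before_comps), {(side, dst)}) \
            if before_comps else {(side, dst)}

        def undo():
            self.fams[side][dst]["members"].discard(pos)
            self.fams[side][src]["members"].add(pos)
            self.assign[side][pos] = src
            if new_fam:
                del self.fams[side][dst]

        def extra():
            if src_empty:
                self._drop_empty(side, src)

        return self._finalize(before_comps, before_vals, after_nodes,
                              [(side, k_a, k_b)], undo, extra,
                              extra_delta=bonus_delta)

    def merge(self, rng):
        side = self.SIDES[rng.integers(2)]
        fids = list(self.fams[side])
        if len(fids) < 2:
            return None
        i, j = rng.choice(len(fids), size=2, replace=False)
        fa, fb = fids[int(i)], fids[int(j)]
        pa = self.fams[side][fa]["parent"]
        pb = self.fams[side][fb]["parent"]
        if pa is not None and pb is not None:
            return None
        if pa is None and pb is not None:
            fa, fb = fb, fa  # absorb into the sampled-headed family
        if any(self.locked[side].get(p) == fb
               for p in self.fams[side][fb]["members"]):
            return None
        touched = {(side, fa), (side, fb)}
        before_comps, before_vals = self._affected_eval(touched)
        k_b = self._k(side)
        moved = set(self.fams[side][fb]["members"])
        self.fams[side][fa]["members"] |= moved
        self.fams[side][fb]["members"] = set()
        for pos in moved:
            self.assign[side][pos] = fa
        after_nodes = set().union(*map(set, before_comps))

        def undo():
            self.fams[side][fa]["members"] -= moved
            self.fams[side][fb]["members"] = moved
            for pos in moved:
                self.assign[side][pos] = fb

        def extra():
            self._drop_empty(side, fb)

        return self._finalize(before_comps, before_vals, after_nodes,
                              [(side, k_b - 1, k_b)], undo, extra)

    def split(self, rng):
        side = self.SIDES[rng.integers(2)]
        big = [
            fid for fid, f in self.fams[side].items()
            if len(f["members"]) >= 2
            and any(p not in self.locked[side] for p in f["members"])
        ]
        if not big:
            return None
        fid = big[int(rng.integers(len(big)))]
        movable = [p for p in self.fams[side][fid]["members"]
                   if p not in self.locked[side]]
        k = int(rng.integers(1, len(movable) + 1))
        moved = set(int(x) for x in rng.choice(movable, size=k, replace=False))
        if moved == self.fams[side][fid]["members"] and \
                self.fams[side][fid]["parent"] is not None:
            return None  # don't orphan a sampled head entirely
        touched = {(side, fid)}
        before_comps, before_vals = self._affected_eval(touched)
        k_b = self._k(side)
        new = self._new_fam(side, set(moved), None)
        self.fams[side][fid]["members"] -= moved
        emptied = not self.fams[side][fid]["members"]
        k_a = k_b + 1 - (1 if emptied else 0)
        after_nodes = set().union(*map(set, before_comps), {(side, new)})

        def undo():
            self.fams[side][fid]["members"] |= moved
            for pos in moved:
                self.assign[side][pos] = fid
            del self.fams[side][new]

        def extra():
            if emptied:
                self._drop_empty(side, fid)

        return self._finalize(before_comps, before_vals, after_nodes,
                              [(side, k_a, k_b)], undo, extra)

    def swap_parent(self, rng):
        side = self.SIDES[rng.integers(2)]
        fids = list(self.fams[side])
        fid = fids[int(rng.integers(len(fids)))]
        fam = self.fams[side][fid]
        if any(self.locked[side].get(p) == fid for p in fam["members"]):
            return None
        old = fam["parent"]
        if old is None:
            if not self.free[side]:
                return None
            new = self.free[side][int(rng.integers(len(self.free[side])))]
        else:
            new = None
        touched = {(side, fid)}
        before_comps, before_vals = self._affected_eval(touched)
        fam["parent"] = new
        bonus_delta = self.bonus[side] * ((new is not None) - (old is not None))

        def undo():
            fam["parent"] = old

        def extra():
            if old is None:
                self.free[side].remove(new)
            else:
                self.free[side].append(old)

        delta, undo_, commit = self._finalize(
            before_comps, before_vals,
            set().union(*map(set, before_comps)), [], undo, extra,
        )
        return delta + bonus_delta, undo_, commit

    # ---------------------------------------------------------------- search
    def anneal(self, rng, n_steps, t0=2.0, t_min=0.02):
        best = self.score
        best_state = self.snapshot()
        cool = (t_min / t0) ** (1.0 / max(n_steps - 1, 1))
        t = t0
        movers = [self.move_offspring, self.merge, self.split, self.swap_parent]
        weights = np.array([0.5, 0.2, 0.2, 0.1])
        for _ in range(n_steps):
            res = movers[int(rng.choice(4, p=weights))](rng)
            t *= cool
            if res is None:
                continue
            delta, undo, commit = res
            if delta >= 0 or rng.random() < math.exp(delta / max(t, 1e-9)):
                commit()
                self.score += delta
                if self.score > best + 1e-12:
                    best = self.score
                    best_state = self.snapshot()
            else:
                undo()
        self.restore(best_state)
        self.greedy_polish()
        return self.score

    def greedy_polish(self, max_sweeps=20):
        for _ in range(max_sweeps):
            improved = False
            for side in self.SIDES:
                for pos in range(self.n):
                    if pos in self.locked[side]:
                        continue
                    if self._best_move(side, pos):
                        improved = True
                for fid in list(self.fams[side]):
                    if self._best_parent(side, fid):
                        improved = True
            if not improved:
                break

    def _try_move(self, side, pos, dst):
        """Delta for moving ``pos`` to family ``dst`` (None = new latent)."""
        src = self.assign[side][pos]
        if dst == src:
            return None
        touched = {(side, src)} | ({(side, dst)} if dst is not None else set())
        before_comps, before_vals = self._affected_eval(touched)
        k_b = self._k(side)
        new_fam = dst is None
        if new_fam:
            dst = self._new_fam(side, set(), None)
        self.fams[side][src]["members"].discard(pos)
        self.fams[side][dst]["members"].add(pos)
        self.assign[side][pos] = dst
        src_empty = not self.fams[side][src]["members"]
        k_a = k_b + (1 if new_fam else 0) - (1 if src_empty else 0)
        bonus_delta = (
            -self.bonus[side]
            if src_empty and self.fams[side][src]["parent"] is not None
            else 0.0
        )
        after_nodes = set().union(*map(set, before_comps), {(side, dst)})

        def undo():
            self.fams[side][dst]["members"].discard(pos)
            self.fams[side][src]["members"].add(pos)
            self.assign[side][pos] = src
            if new_fam:
                del self.fams[side][dst]

        def extra():
            if src_empty:
                self._drop_empty(side, src)

        return self._finalize(before_comps, before_vals, after_nodes,
                              [(side, k_a, k_b)], undo, extra,
                              extra_delta=bonus_delta)

    _NEW = object()  # sentinel: move into a brand-new latent family

    def _best_move(self, side, pos) -> bool:
        options = [fid for fid in self.fams[side]
                   if fid != self.assign[side][pos]] + [self._NEW]
        best_delta, best_opt = 1e-9, None
        for opt in options:
            res = self._try_move(side, pos, None if opt is self._NEW else opt)
            if res is None:
                continue
            delta, undo, _commit = res
            undo()
            if delta > best_delta:
                best_delta, best_opt = delta, opt
        if best_opt is None:
            return False
        delta, _undo, commit = self._try_move(
            side, pos, None if best_opt is self._NEW else best_opt
        )
        commit()
        self.score += delta
        return True

    def _best_parent(self, side, fid) -> bool:
        fam = self.fams[side].get(fid)
        if fam is None or not fam["members"]:
            return False
        if any(self.locked[side].get(p) == fid for p in fam["members"]):
            return False
        current = fam["parent"]
        options = [None] + list(self.free[side])
        best_delta, best_parent = 1e-9, current
        touched = {(side, fid)}
        before_comps, before_vals = self._affected_eval(touched)
        for cand in options:
            if cand == current:
                continue
            fam["parent"] = cand
            _, after_vals = self._affected_eval(
                set().union(*map(set, before_comps)), use_cache=False
            )
            delta = sum(v for _, v in after_vals) - \
                sum(v for _, v in before_vals)
            delta += self.bonus[side] * ((cand is not None) - (current is not None))
            if delta > best_delta:
                best_delta, best_parent = delta, cand
            fam["parent"] = current
        if best_parent != current:
            fam["parent"] = best_parent
            comps, vals = self._affected_eval(
                set().union(*map(set, before_comps)), use_cache=False
            )
            for c in before_comps:
                self._cache.pop(c, None)
            for c, v in vals:
                self._cache[c] = v
            if current is None:
                self.free[side].remove(best_parent)
            else:
                self.free[side].append(current)
            self.score += best_delta
            return True
        return False

    # ------------------------------------------------------------- plumbing
    def snapshot(self):
        return (
            {
                s: {fid: (set(f["members"]), f["parent"])
                    for fid, f in self.fams[s].items()}
                for s in self.SIDES
            },
            {s: dict(self.assign[s]) for s in self.SIDES},
            {s: list(self.free[s]) for s in self.SIDES},
            dict(self._next),
            self.score,
        )

    def restore(self, snap) -> None:
        fams, assign, free, nxt, score = snap
        self.fams = {
            s: {fid: {"members": set(m), "parent": p}
                for fid, (m, p) in fams[s].items()}
            for s in self.SIDES
        }
        self.assign = {s: dict(assign[s]) for s in self.SIDES}
        self.free = {s: list(free[s]) for s in self.SIDES}
        self._next = dict(nxt)
        self._cache = {}
        self.score = score

    def to_refs(self, side, latent_prefix) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        latent = 0
        fams = sorted(
            self.fams[side].items(),
            key=lambda kv: (-len(kv[1]["members"]), kv[0]),
        )
        for fid, fam in fams:
            if not fam["members"]:
                continue
            if fam["parent"] is not None:
                ref = fam["parent"]
            else:
                latent += 1
                ref = f"{latent_prefix}{latent}"
            out[ref] = sorted(self.offspring[p] for p in fam["members"])
        return out


def sibship_reconstruct(
    scorer: ParentageScorer,
    offspring_ids: Sequence[str],
    candidate_mothers: Sequence[str] = (),
    candidate_fathers: Sequence[str] = (),
    known_assignments: Sequence[ParentageAssignment] | None = None,
    prior_father_sampled: float = 0.5,
    prior_mother_sampled: float = 0.25,
    pool_mothers: int | None = None,
    pool_fathers: int | None = None,
    n_replicates: int = 3,
    seed: int | None = None,
    steps_per_offspring_sq: float = 12.0,
    min_steps: int = 4000,
) -> SibshipResult:
    """Full-likelihood sibship + parentage by simulated annealing.

    The joint maternal x paternal configuration is searched with moves
    {move offspring between families, split family, merge families, swap a
    family's head between sampled candidates and a latent parent}; each
    replicate runs an independent annealing chain from a different seed,
    followed by a greedy polish.  Known strict-confidence assignments are
    hard constraints.  Returns the best-scoring replicate and the
    cross-replicate pairwise partition agreement.
    """
    offspring_ids = list(offspring_ids)
    known_m = _known_from_assignments(known_assignments, "mother")
    known_f = _known_from_assignments(known_assignments, "father")
    for o, p in known_m.items():
        if p not in candidate_mothers:
            raise ValueError(f"known mother {p!r} not among candidate mothers")
    for o, p in known_f.items():
        if p not in candidate_fathers:
            raise ValueError(f"known father {p!r} not among candidate fathers")
    n = len(offspring_ids)
    n_steps = max(min_steps, int(steps_per_offspring_sq * n * n))
    seed_seq = np.random.SeedSequence(seed)
    solutions = []
    for rep, s in enumerate(seed_seq.spawn(n_replicates)):
        rng = np.random.default_rng(s)
        state = _JointSibshipState(
            scorer, offspring_ids,
            {"M": list(candidate_mothers), "F": list(candidate_fathers)},
            {"M": prior_mother_sampled, "F": prior_father_sampled},
            {"M": known_m, "F": known_f},
            {"M": pool_mothers, "F": pool_fathers},
        )
        score = state.anneal(rng, n_steps)
        solutions.append(
            SibshipSolution(
                offspring=offspring_ids,
                maternal_families=state.to_refs("M", "#"),
                paternal_families=state.to_refs("F", "*"),
                loglik=score,
                seed=int(s.generate_state(1)[0] % (2**31)),
                replicate=rep,
            )
        )
    best = max(solutions, key=lambda sol: sol.loglik)
    return SibshipResult(
        best=best,
        replicates=solutions,
        pairwise_agreement=_replicate_agreement(solutions),
    )


def _partition_labels(sol: SibshipSolution, side: str) -> dict[str, str]:
    fams = sol.maternal_families if side == "mother" else sol.paternal_families
    return {o: ref for ref, members in fams.items() for o in members}


def _replicate_agreement(solutions: Sequence[SibshipSolution]) -> float:
    if len(solutions) < 2:
        return 1.0
    offspring = solutions[0].offspring
    pairs = list(itertools.combinations(offspring, 2))
    if not pairs:
        return 1.0
    agree = []
    for side in ("mother", "father"):
        labels = [_partition_labels(s, side) for s in solutions]
        for la, lb in itertools.combinations(labels, 2):
            same_a = np.array([la[x] == la[y] for x, y in pairs])
            same_b = np.array([lb[x] == lb[y] for x, y in pairs])
            agree.append(float(np.mean(same_a == same_b)))
    return float(np.mean(agree))


def configuration_score(
    scorer: ParentageScorer,
    maternal_families: Sequence[tuple[str | None, Sequence[str]]],
    paternal_families: Sequence[tuple[str | None, Sequence[str]]],
    prior_mother_sampled: float = 0.25,
    prior_father_sampled: float = 0.5,
    n_candidate_mothers: int = 0,
    n_candidate_fathers: int = 0,
    pool_mothers: int | None = None,
    pool_fathers: int | None = None,
) -> float:
    """Score an explicit configuration with the same exact joint likelihood
    and priors the annealer optimises.  Families are (head-or-None,
    offspring id list); every offspring must appear once per side."""
    state, _refs = _state_from_families(
        scorer, maternal_families, paternal_families,
        prior_mother_sampled, prior_father_sampled,
        n_candidate_mothers, n_candidate_fathers,
        pool_mothers, pool_fathers,
    )
    return state.total_score()


def _state_from_families(
    scorer,
    maternal_families,
    paternal_families,
    prior_mother_sampled=0.25,
    prior_father_sampled=0.5,
    n_candidate_mothers=0,
    n_candidate_fathers=0,
    pool_mothers=None,
    pool_fathers=None,
    refs=None,
):
    """Build a frozen :class:`_JointSibshipState` from explicit families.

    ``refs`` optionally names each family (parallel to the family lists);
    returns (state, {node: ref}).
    """
    offspring = sorted({o for _, mem in maternal_families for o in mem})
    state = _JointSibshipState.__new__(_JointSibshipState)
    state.sc = scorer
    state.offspring = offspring
    state.rows = np.array([scorer.ind_index[o] for o in offspring])
    state.n = len(offspring)
    pos_of = {o: i for i, o in enumerate(offspring)}
    state.cand = {"M": [], "F": []}
    state.bonus = {}
    state._prior_cum = {}
    state.pool = {}
    state.fams = {s: {} for s in state.SIDES}
    state.assign = {s: {} for s in state.SIDES}
    state.locked = {s: {} for s in state.SIDES}
    state.free = {s: [] for s in state.SIDES}
    state._next = {s: 0 for s in state.SIDES}
    state._cache = {}
    ref_of_node = {}
    for s, fams, prior, n_cand, pool in (
        ("M", maternal_families, prior_mother_sampled, n_candidate_mothers,
         pool_mothers),
        ("F", paternal_families, prior_father_sampled, n_candidate_fathers,
         pool_fathers),
    ):
        nc = max(n_cand, 1)
        state.bonus[s] = (
            math.log(prior) - math.log(max(1.0 - prior, 1e-12)) - math.log(nc)
        )
        ps = pool if pool is not None else n_cand + state.n
        state.pool[s] = max(int(ps), 1)
        kmax = state.n + nc + 1
        terms = np.log(
            np.clip(state.pool[s] - np.arange(kmax, dtype=float), 0.25, None)
        )
        state._prior_cum[s] = np.concatenate([[0.0], np.cumsum(terms)])
        side_refs = None if refs is None else refs[s]
        for i, (head, members) in enumerate(fams):
            fid = state._new_fam(s, {pos_of[o] for o in members}, head)
            if side_refs is not None:
                ref_of_node[(s, fid)] = side_refs[i]
    return state, ref_of_node


def exhaustive_sibship(
    scorer: ParentageScorer,
    offspring_ids: Sequence[str],
    candidate_mothers: Sequence[str] = (),
    candidate_fathers: Sequence[str] = (),
    prior_father_sampled: float = 0.5,
    prior_mother_sampled: float = 0.25,
    pool_mothers: int | None = None,
    pool_fathers: int | None = None,
    max_offspring: int = 6,
) -> tuple[float, SibshipSolution]:
    """Brute-force the joint maternal x paternal configuration space.

    Enumerates every pair of set partitions (and every injective attachment
    of sampled candidates to families), scoring each with the same exact
    configuration likelihood the annealer uses.  The small-instance oracle:
    n <= ``max_offspring``.
    """
    offspring_ids = list(offspring_ids)
    n = len(offspring_ids)
    if n > max_offspring:
        raise ValueError("exhaustive search limited to small offspring sets")

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield part + [[first]]

    all_parts = [
        [tuple(b) for b in part] for part in partitions(list(range(n)))
    ]

    def head_options(part, candidates):
        n_fam = len(part)
        yield tuple([None] * n_fam)
        for k in range(1, min(len(candidates), n_fam) + 1):
            for fam_idx in itertools.combinations(range(n_fam), k):
                for cand_perm in itertools.permutations(candidates, k):
                    heads = [None] * n_fam
                    for fi, c in zip(fam_idx, cand_perm):
                        heads[fi] = c
                    yield tuple(heads)

    best_score, best_cfg = -math.inf, None
    for mpart in all_parts:
        for mheads in head_options(mpart, list(candidate_mothers)):
            mfams = [
                (h, [offspring_ids[p] for p in block])
                for h, block in zip(mheads, mpart)
            ]
            for fpart in all_parts:
                for fheads in head_options(fpart, list(candidate_fathers)):
                    ffams = [
                        (h, [offspring_ids[p] for p in block])
                        for h, block in zip(fheads, fpart)
                    ]
                    score = configuration_score(
                        scorer, mfams, ffams,
                        prior_mother_sampled, prior_father_sampled,
                        len(candidate_mothers), len(candidate_fathers),
                        pool_mothers, pool_fathers,
                    )
                    if score > best_score:
                        best_score = score
                        best_cfg = (mfams, ffams)

    def refs(fams, prefix):
        out = {}
        latent = 0
        for head, members in sorted(fams, key=lambda hf: -len(hf[1])):
            if not members:
                continue
            if head is not None:
                ref = head
            else:
                latent += 1
                ref = f"{prefix}{latent}"
            out[ref] = sorted(members)
        return out

    sol = SibshipSolution(
        offspring=offspring_ids,
        maternal_families=refs(best_cfg[0], "#"),
        paternal_families=refs(best_cfg[1], "*"),
        loglik=best_score,
    )
    return best_score, sol


def reconstruct_parent_genotypes(
    solution: SibshipSolution,
    scorer: ParentageScorer,
    tie_tol: float = 1e-9,
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """ML genotypes of every latent parent, per locus, with tied sets.

    Works on the same bipartite family graph as the configuration
    likelihood: per component and per locus, a two-pass max-product
    (belief revision) computes every latent parent's max-marginal over its
    genotype — sampled co-parents enter through their observed-genotype
    weights, latent co-parents through the messages of the tree.  All
    genotypes whose max-marginal ties the optimum within ``tie_tol`` (log
    scale) are reported as the ambiguity set.  The rare cyclic components
    fall back to per-parent conditional posteriors.
    """
    m_fams = [(None if ref.startswith("#") else ref, members)
              for ref, members in solution.maternal_families.items() if members]
    f_fams = [(None if ref.startswith("*") else ref, members)
              for ref, members in solution.paternal_families.items() if members]
    refs = {
        "M": [ref for ref, mem in solution.maternal_families.items() if mem],
        "F": [ref for ref, mem in solution.paternal_families.items() if mem],
    }
    state, ref_of_node = _state_from_families(
        scorer, m_fams, f_fams, refs=refs
    )
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for comp in state._comps_containing(state.all_nodes()):
        latents = [
            n for n in comp
            if state.fams[n[0]][n[1]]["parent"] is None
        ]
        if not latents:
            continue
        marginals = _component_max_marginals(state, comp)
        for node in latents:
            ref = ref_of_node[node]
            per_locus: dict[str, list[tuple[int, int]]] = {}
            for l, locus in enumerate(scorer.loci):
                m = scorer.models[locus]
                logmm = marginals[node][l]
                top = float(np.max(logmm))
                tied = np.flatnonzero(logmm >= top - tie_tol)
                per_locus[locus] = [
                    (int(m.alleles[m.genotypes[g][0]]),
                     int(m.alleles[m.genotypes[g][1]]))
                    for g in tied
                ]
            out[ref] = per_locus
    return out


def _component_max_marginals(state, comp):
    """Per-node, per-locus log max-marginals over family-head genotypes.

    Two-pass max-product message passing on the component's spanning tree
    (cut matings folded into the parents' priors as in the likelihood).
    """
    lin_priors, adj, lin_pots, _logconst = state._comp_tree(comp)
    nodes = list(comp)
    priors = {
        n: np.log(np.maximum(lin_priors[n], 1e-300)) for n in nodes
    }
    pots = {
        key: np.log(np.maximum(E, 1e-300)).astype(np.float64)
        for key, E in lin_pots.items()
    }

    def edge_pot(x, y):
        """Log potential oriented so axis 1 is x's genotype, axis 2 y's."""
        if (x, y) in pots:
            return pots[(x, y)]
        return np.transpose(pots[(y, x)], (0, 2, 1))

    # two-pass max-product on the tree
    root = nodes[0]
    order = []
    parent_of = {root: None}
    stack = [root]
    while stack:
        cur = stack.pop()
        order.append(cur)
        for nb in adj[cur]:
            if nb not in parent_of:
                parent_of[nb] = cur
                stack.append(nb)
    up_msg: dict[tuple, np.ndarray] = {}
    for node in reversed(order):  # leaves first
        par = parent_of[node]
        if par is None:
            continue
        belief = priors[node].copy()
        for nb in adj[node]:
            if nb != par:
                belief = belief + up_msg[nb]
        E = edge_pot(node, par)
        up_msg[node] = np.max(belief[:, :, None] + E, axis=1)
    down_msg: dict[tuple, np.ndarray] = {root: np.zeros_like(priors[root])}
    for node in order:  # root first
        for child in adj[node]:
            if parent_of.get(child) != node:
                continue
            belief = priors[node] + down_msg[node]
            for other in adj[node]:
                if other != child and parent_of.get(other) == node:
                    belief = belief + up_msg[other]
            if parent_of[node] is not None:
                pass  # down_msg[node] already contains everything above
            E = edge_pot(node, child)
            down_msg[child] = np.max(belief[:, :, None] + E, axis=1)
    out = {}
    for node in nodes:
        belief = priors[node] + down_msg[node]
        for nb in adj[node]:
            if parent_of.get(nb) == node:
                belief = belief + up_msg[nb]
        out[node] = belief
    return out


# ------------------------------------------------------------------ counting


@dataclass
class BreederCount:
    mothers_sampled: int
    fathers_sampled: int
    mothers_reconstructed: int
    fathers_reconstructed: int

    @property
    def total(self) -> int:
        return (
            self.mothers_sampled
            + self.fathers_sampled
            + self.mothers_reconstructed
            + self.fathers_reconstructed
        )


def count_breeders(
    solution: SibshipSolution,
    assignments: Sequence[ParentageAssignment] | None = None,
) -> BreederCount:
    """Distinct sampled and reconstructed parents with >=1 offspring.

    Sampled parents come from the sibship solution's sampled-headed families
    plus any strict-confidence direct assignments; reconstructed parents are
    the solution's non-empty latent families.
    """
    m_sampled = {r for r, mem in solution.maternal_families.items()
                 if mem and not r.startswith("#")}
    f_sampled = {r for r, mem in solution.paternal_families.items()
                 if mem and not r.startswith("*")}
    if assignments:
        for a in assignments:
            if a.mother_ref is not None and a.confidence_mother == "strict95":
                m_sampled.add(a.mother_ref)
            if a.father_ref is not None and a.confidence_father == "strict95":
                f_sampled.add(a.father_ref)
    m_latent = sum(
        1 for r, mem in solution.maternal_families.items() if mem and r.startswith("#")
    )
    f_latent = sum(
        1 for r, mem in solution.paternal_families.items() if mem and r.startswith("*")
    )
    return BreederCount(
        mothers_sampled=len(m_sampled),
        fathers_sampled=len(f_sampled),
        mothers_reconstructed=m_latent,
        fathers_reconstructed=f_latent,
    )


# -------------------------------------------------------------------- litters


@dataclass
class Litter:
    mother_ref: str
    cohort_year: int | None
    offspring: list[str]
    sires: set[str] = field(default_factory=set)
    sites: set[str] = field(default_factory=set)


@dataclass
class LitterSummary:
    litters: list[Litter]
    unknown_year: list[Litter]
    polyandry_fraction: float | None
    n_multi_young: int
    n_polyandrous: int
    litters_per_father: Counter
    fraction_fathers_multi_litter: float | None
    #: mothers with >=2 dated litters whose litters all share a nursery site
    mothers_repeat_nursery: int = 0
    #: mothers with >=2 dated litters, all consecutive gaps exactly 2 years
    mothers_biennial: int = 0
    #: (father, year) combinations siring litters of >=2 distinct mothers
    multi_female_years: int = 0


def litter_table(
    solution: SibshipSolution,
    meta: Mapping[str, IndividualMeta],
) -> LitterSummary:
    """Litters (same mother x same cohort year) with sire sets and summaries.

    Offspring of unknown cohort year are listed separately and excluded from
    the cycle statistics.  Polyandry fraction = multi-sire multi-young
    litters / multi-young litters (None when no multi-young litters exist).
    """
    father_of = {
        o: ref for ref, members in solution.paternal_families.items() for o in members
    }
    litters: list[Litter] = []
    unknown: list[Litter] = []
    for mref, members in solution.maternal_families.items():
        by_year: dict[int | None, list[str]] = {}
        for o in members:
            year = meta[o].cohort_year if o in meta else None
            by_year.setdefault(year, []).append(o)
        for year, offs in sorted(by_year.items(), key=lambda kv: (kv[0] is None, kv[0] or 0)):
            lit = Litter(
                mother_ref=mref,
                cohort_year=year,
                offspring=sorted(offs),
                sires={father_of[o] for o in offs if o in father_of},
                sites={meta[o].site for o in offs if o in meta and meta[o].site},
            )
            (unknown if year is None else litters).append(lit)
    multi = [l for l in litters if len(l.offspring) >= 2]
    poly = [l for l in multi if len(l.sires) >= 2]
    per_father: Counter = Counter()
    for l in litters:
        for sire in l.sires:
            per_father[sire] += 1
    frac_multi_father = (
        sum(1 for c in per_father.values() if c >= 2) / len(per_father)
        if per_father
        else None
    )
    by_mother: dict[str, list[Litter]] = {}
    for l in litters:
        by_mother.setdefault(l.mother_ref, []).append(l)
    repeat_nursery = biennial = 0
    for lits in by_mother.values():
        if len(lits) < 2:
            continue
        sites = [s for l in lits for s in l.sites]
        if sites and len(set(sites)) == 1:
            repeat_nursery += 1
        years = sorted(l.cohort_year for l in lits)
        if all(b - a == 2 for a, b in zip(years, years[1:])):
            biennial += 1
    father_year_mothers: dict[tuple, set] = {}
    for l in litters:
        for sire in l.sires:
            father_year_mothers.setdefault((sire, l.cohort_year), set()).add(
                l.mother_ref
            )
    multi_female_years = sum(
        1 for mothers in father_year_mothers.values() if len(mothers) >= 2
    )
    return LitterSummary(
        litters=litters,
        unknown_year=unknown,
        polyandry_fraction=(len(poly) / len(multi)) if multi else None,
        n_multi_young=len(multi),
        n_polyandrous=len(poly),
        litters_per_father=per_father,
        fraction_fathers_multi_litter=frac_multi_father,
        mothers_repeat_nursery=repeat_nursery,
        mothers_biennial=biennial,
        multi_female_years=multi_female_years,
    )
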