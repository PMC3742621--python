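"""Parentage assignment, sibship reconstruction and breeder counting.

Stage 1 scores every juvenile against every sampled adult of each sex
(LOD), with strict-95% Delta thresholds calibrated by simulation (sampled-
parent priors 0.25 for mothers, 0.5 for fathers).  Stage 2 reconstructs
maternal and paternal sibships by simulated annealing (three replicate
runs, different seeds), treating the strict assignments as known
parentages, then reconstructs latent parental genotypes, counts breeders,
and tabulates litters (mother x cohort year) with sire sets.

The partition prior's pool sizes are the investigator's guess of the
breeding population per sex; here ~1.5x the photo-identified adult census
(33 potential mothers, 27 potential fathers).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from kinnet.genotypes import read_genotypes, read_metadata
from kinnet.parentage import (
    ParentageScorer,
    assign_parents,
    count_breeders,
    delta_criticals,
    litter_table,
    reconstruct_parent_genotypes,
    sibship_reconstruct,
)
from kinnet.qc import allele_frequencies


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genotypes", type=Path,
                    default=Path("results/qc/genotypes_retained.gen"))
    ap.add_argument("--meta", type=Path, default=Path("results/fixture/metadata.csv"))
    ap.add_argument("--error", type=float, default=0.01)
    ap.add_argument("--prior-father", type=float, default=0.5)
    ap.add_argument("--prior-mother", type=float, default=0.25)
    ap.add_argument("--pool-mothers", type=int, default=33)
    ap.add_argument("--pool-fathers", type=int, default=27)
    ap.add_argument("--replicates", type=int, default=3)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/parentage"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_genotypes(args.genotypes)
    meta = read_metadata(args.meta)
    adults = [i for i in table.individuals if meta[i].stage == "mature"]
    juveniles = [i for i in table.individuals if meta[i].stage != "mature"]
    mothers = sorted(i for i in adults if meta[i].sex == "F")
    fathers = sorted(i for i in adults if meta[i].sex == "M")
    freqs = allele_frequencies(table)
    scorer = ParentageScorer(table, freqs, args.error)

    crit_m = delta_criticals(freqs, len(mothers), args.prior_mother,
                             error_rate=args.error, seed=args.seed)
    crit_f = delta_criticals(freqs, len(fathers), args.prior_father,
                             error_rate=args.error, seed=args.seed + 1)
    print(f"strict-95% Delta thresholds: mothers {crit_m:.2f}, fathers {crit_f:.2f}")
    assignments = assign_parents(scorer, juveniles, mothers, fathers,
                                 {"mother": crit_m, "father": crit_f})
    outcomes = pd.Series([a.outcome for a in assignments]).value_counts()
    n_any = int((outcomes.drop("unassigned", errors="ignore")).sum())
    print(f"{n_any}/{len(juveniles)} juveniles assigned to at least one "
          f"sampled parent: {outcomes.to_dict()}")
    pd.DataFrame([vars(a) for a in assignments]).to_csv(
        args.out / "assignments.csv", index=False
    )

    res = sibship_reconstruct(
        scorer, juveniles, mothers, fathers, known_assignments=assignments,
        prior_father_sampled=args.prior_father,
        prior_mother_sampled=args.prior_mother,
        pool_mothers=args.pool_mothers, pool_fathers=args.pool_fathers,
        n_replicates=args.replicates, seed=args.seed,
    )
    print(f"sibship replicate agreement: {res.pairwise_agreement:.3f}")
    (args.out / "sibship.json").write_text(json.dumps({
        "maternal_families": res.best.maternal_families,
        "paternal_families": res.best.paternal_families,
        "loglik": res.best.loglik,
        "replicate_agreement": res.pairwise_agreement,
    }, indent=1))

    recon = reconstruct_parent_genotypes(res.best, scorer)
    pd.DataFrame([
        {"parent": p, "locus": locus,
         "genotypes": ";".join(f"{a}/{b}" for a, b in options)}
        for p, per_locus in recon.items()
        for locus, options in per_locus.items()
    ]).to_csv(args.out / "reconstructed_parents.csv", index=False)

    bc = count_breeders(res.best, assignments)
    (args.out / "breeders.json").write_text(json.dumps({
        "mothers_sampled": bc.mothers_sampled,
        "fathers_sampled": bc.fathers_sampled,
        "mothers_reconstructed": bc.mothers_reconstructed,
        "fathers_reconstructed": bc.fathers_reconstructed,
        "total": bc.total,
    }, indent=1))
    print(f"breeders: {bc.mothers_sampled}+{bc.mothers_reconstructed} mothers, "
          f"{bc.fathers_sampled}+{bc.fathers_reconstructed} fathers, "
          f"total {bc.total}")

    lt = litter_table(res.best, meta)
    pd.DataFrame([
        {"mother_ref": l.mother_ref, "cohort_year": l.cohort_year,
         "n_offspring": len(l.offspring), "offspring": ";".join(l.offspring),
         "sires": ";".join(sorted(l.sires)), "sites": ";".join(sorted(l.sites))}
        for l in lt.litters + lt.unknown_year
    ]).to_csv(args.out / "litters.csv", index=False)
    poly = "undefined" if lt.polyandry_fraction is None else f"{lt.polyandry_fraction:.0%}"
    print(f"{len(lt.litters)} litters; polyandry among multi-young litters: "
          f"{poly} ({lt.n_polyandrous}/{lt.n_multi_young}); "
          f"fathers with multiple litters: {lt.fraction_fathers_multi_litter:.0%}")


if __name__ == "__main__":
    main()
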