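"""Pairwise ML relatedness and the adult first-order genetic network.

Estimates (k0, k1, k2) and r-hat for every adult dyad, classifies each dyad
into U/HS/FS/PO, screens first-order calls against a pooled simulated null
(Holm-corrected), builds the first-order network, and runs the within- vs
between-group relatedness permutation test (residency groups, then sex).
"""

import argparse
import json
from pathlib import Path

from kinnet.genotypes import read_genotypes, read_metadata
from kinnet.network import (
    build_network,
    degree_distribution,
    export_network,
    first_order_fraction,
    group_relatedness_test,
)
from kinnet.relatedness import (
    PairScorer,
    mean_sd_offdiag,
    relatedness_matrix,
    significance_filter,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--genotypes", type=Path,
                    default=Path("results/qc/genotypes_retained.gen"))
    ap.add_argument("--meta", type=Path, default=Path("results/fixture/metadata.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=20000)
    ap.add_argument("--out", type=Path, default=Path("results/network"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = read_genotypes(args.genotypes)
    meta = read_metadata(args.meta)
    adults = sorted(i for i in table.individuals if meta[i].stage == "mature")
    res = relatedness_matrix(table, ids=adults)
    mean, sd = mean_sd_offdiag(res.r)
    print(f"adult dyads: {len(res.dyads)}; mean R = {mean:.3f} +/- {sd:.3f}")
    frac = first_order_fraction(res.dyads)
    print(f"first-order (PO/FS/HS) fraction of dyads: {frac:.1%}")

    scorer = PairScorer(table)
    dyads = significance_filter(scorer, res.dyads, seed=args.seed)
    dyads.to_csv(args.out / "dyads.csv", index=False)
    res.r.to_csv(args.out / "r_matrix.csv")

    g = build_network(dyads, meta, require_significant=True)
    export_network(g, args.out / "network.graphml", "graphml")
    export_network(g, args.out / "edges.csv", "edge_csv")
    degrees, hist, dmean, dsd = degree_distribution(g)
    isolated = sorted(n for n, d in g.degree() if d == 0)
    print(f"network: {g.number_of_edges()} significant first-order edges; "
          f"degree {dmean:.1f} +/- {dsd:.1f}; isolated: {isolated or 'none'}")

    groups = {i: meta[i].group for i in adults}
    gt = group_relatedness_test(res.r, groups, n_perm=args.n_perm, seed=args.seed)
    sexes = {i: meta[i].sex for i in adults}
    st = group_relatedness_test(res.r, sexes, n_perm=args.n_perm, seed=args.seed + 1)
    (args.out / "group_tests.json").write_text(json.dumps({
        "residency": {"mean_within": gt.mean_within,
                      "mean_between": gt.mean_between, "p": gt.p},
        "sex": {"mean_within": st.mean_within,
                "mean_between": st.mean_between, "p": st.p},
        "n_perm": args.n_perm,
    }, indent=1))
    print(f"group relatedness test (residency): p = {gt.p:.4g}; (sex): p = {st.p:.4g}")


if __name__ == "__main__":
    main()
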