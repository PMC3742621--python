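"""First-order genetic networks and group-relatedness permutation tests.

Nodes are individuals (with sex / length / group metadata); edges connect
only dyads whose best relationship category is first order (PO, FS or HS),
weighted by the ML relatedness r-hat.  Isolated nodes are kept — an
unconnected individual is itself a finding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import IndividualMeta
from .relatedness import FIRST_ORDER

__all__ = [
    "build_network",
    "degree_distribution",
    "first_order_fraction",
    "group_relatedness_test",
    "export_network",
    "import_network",
    "GroupTestResult",
]


def build_network(
    dyads: pd.DataFrame,
    meta: Mapping[str, IndividualMeta] | None = None,
    individuals: Sequence[str] | None = None,
    require_significant: bool = False,
) -> nx.Graph:
    """Build the first-order genetic network from a dyad table.

    ``dyads`` needs columns id_a, id_b, r_hat, best_category (and
    ``significant`` when ``require_significant``).  One node per individual
    appearing in the dyad table (or in ``individuals``), isolated nodes
    kept; one edge per first-order dyad, weight = r_hat, label = category.
    """
    g = nx.Graph()
    nodes = set(dyads["id_a"]) | set(dyads["id_b"])
    if individuals is not None:
        unknown = nodes - set(individuals)
        if unknown:
            raise ValueError(f"dyads reference unknown individuals: {sorted(unknown)}")
        nodes = set(individuals)
    for node in sorted(nodes):
        attrs = {}
        if meta and node in meta:
            m = meta[node]
            attrs = {
                "sex": m.sex,
                "total_length_cm": float("nan")
                if m.total_length_cm is None
                else m.total_length_cm,
                "group": m.group or "",
                "site": m.site or "",
                "stage": m.stage or "",
            }
        g.add_node(node, **attrs)
    for row in dyads.itertuples():
        if row.best_category not in FIRST_ORDER:
            continue
        if require_significant and not bool(getattr(row, "significant", False)):
            continue
        g.add_edge(
            row.id_a,
            row.id_b,
            weight=float(row.r_hat),
            category=row.best_category,
        )
    return g


def degree_distribution(g: nx.Graph):
    """Per-node genetic degree plus histogram and mean ± SD over all nodes."""
    degrees = pd.Series(dict(g.degree()), dtype=int).sort_index()
    hist = degrees.value_counts().sort_index()
    mean = float(degrees.mean()) if len(degrees) else 0.0
    sd = float(degrees.std(ddof=1)) if len(degrees) > 1 else 0.0
    return degrees, hist, mean, sd


def first_order_fraction(
    dyads: pd.DataFrame, subset: Sequence[str] | None = None
) -> float:
    """Fraction of dyads (within ``subset`` if given) classified first order."""
    d = dyads
    if subset is not None:
        subset = set(subset)
        if not subset:
            raise ValueError("empty subset")
        d = d[d["id_a"].isin(subset) & d["id_b"].isin(subset)]
    if len(d) == 0:
        raise ValueError("no dyads in subset")
    return float(d["best_category"].isin(FIRST_ORDER).mean())


@dataclass
class GroupTestResult:
    mean_within: float
    mean_between: float
    statistic: float
    p: float
    n_perm: int
    groups_used: list[str]


def group_relatedness_test(
    r: pd.DataFrame,
    groups: Mapping[str, str],
    n_perm: int = 20_000,
    seed: int | None = None,
    exclude_group: str | None = None,
    two_sided: bool = True,
) -> GroupTestResult:
    """Permutation test of within- vs between-group mean relatedness.

    The statistic is mean(within-group dyads) − mean(between-group dyads);
    the null permutes group labels over individuals.  Groups with fewer than
    two members are dropped from the within mean with a warning.  p-values
    use the add-one rule; two-sided by default.  ``exclude_group`` removes a
    named group (and its members) entirely before testing.
    """
    ids = [i for i in r.index if i in groups]
    if exclude_group is not None:
        ids = [i for i in ids if groups[i] != exclude_group]
    labels = np.array([groups[i] for i in ids])
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < 2]
    if small.size:
        warnings.warn(
            f"groups with <2 members dropped from the within mean: {list(small)}"
        )
        keep = ~np.isin(labels, small)
        ids = [i for i, k in zip(ids, keep) if k]
        labels = labels[keep]
        uniq = uniq[counts >= 2]
    if len(uniq) < 2:
        raise ValueError("need at least two groups with >=2 members")
    mat = r.loc[ids, ids].to_numpy(dtype=float)
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    vals = mat[iu]
    ok = ~np.isnan(vals)

    def stat(lab: np.ndarray) -> float:
        same = (lab[iu[0]] == lab[iu[1]])[ok]
        v = vals[ok]
        if not same.any() or same.all():
            return 0.0
        return float(v[same].mean() - v[~same].mean())

    obs = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        s = stat(perm)
        if two_sided:
            if abs(s) >= abs(obs) - 1e-12:
                count += 1
        else:
            if s >= obs - 1e-12:
                count += 1
    p = (count + 1) / (n_perm + 1)
    within_mask = (labels[iu[0]] == labels[iu[1]]) & ok
    between_mask = (labels[iu[0]] != labels[iu[1]]) & ok
    return GroupTestResult(
        mean_within=float(vals[within_mask].mean()),
        mean_between=float(vals[between_mask].mean()),
        statistic=obs,
        p=p,
        n_perm=n_perm,
        groups_used=list(uniq),
    )


def export_network(g: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network as GraphML or an edge-list CSV (weights to 6 dp)."""
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edge_csv":
        rows = [
            {
                "id_a": a,
                "id_b": b,
                "weight": round(float(d.get("weight", 0.0)), 6),
                "category": d.get("category", ""),
            }
            for a, b, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["id_a", "id_b", "weight", "category"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown network format {format!r}")


def import_network(path, format: str = "graphml") -> nx.Graph:
    """Re-read a network written by :func:`export_network` (GraphML only
    round-trips node attributes; edge CSV recovers edges)."""
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edge_csv":
        df = pd.read_csv(path)
        g = nx.Graph()
        for row in df.itertuples():
            g.add_edge(row.id_a, row.id_b, weight=row.weight, category=row.category)
        return g
    raise ValueError(f"unknown network format {format!r}")
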