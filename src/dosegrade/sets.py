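"""Venn set decomposition, Fisher overlap tests and GMT over-representation.

The three per-gene selection flags (WT-regulated, T58A-differential,
T58I-differential) partition the flagged genes into the seven disjoint Venn
regions A-G. Overlaps between gene sets are tested with Fisher's exact test
on the 2x2 table over a stated universe; GMT collections are screened by
hypergeometric over-representation with BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

# region -> (regulated_wt, diff_t58a, diff_t58i)
VENN_REGIONS = {
    "A": (True, False, False),
    "B": (False, True, False),
    "C": (False, False, True),
    "D": (True, True, False),
    "E": (True, False, True),
    "F": (False, True, True),
    "G": (True, True, True),
}


def venn_decompose(flags: pd.DataFrame) -> dict[str, list]:
    """Assign each flagged gene to exactly one region A-G; unflagged genes
    belong to no region."""
    out = {}
    w = flags["regulated_wt"].astype(bool)
    a = flags["diff_t58a"].astype(bool)
    i = flags["diff_t58i"].astype(bool)
    for region, (fw, fa, fi) in VENN_REGIONS.items():
        mask = (w == fw) & (a == fa) & (i == fi) & (w | a | i)
        out[region] = sorted(flags.index[mask])
    return out


@dataclass
class OverlapResult:
    set_x: str
    set_y: str
    n_x: int
    n_y: int
    n_overlap: int
    n_universe: int
    odds_ratio: float
    p: float
    alternative: str
    padj: float | None = None
    direction: str | None = None


def fisher_overlap(x, y, universe, alternative: str = "greater",
                   name_x: str = "x", name_y: str = "y") -> OverlapResult:
    """Fisher's exact test of the overlap between two gene sets.

    Cells: a = |x∩y|, b = |x\\y|, c = |y\\x|, d = rest of the universe.
    The sample odds ratio a*d/(b*c) is reported (inf/0 at zero cells).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    xs = set(x) & uni
    ys = set(y) & uni
    a = len(xs & ys)
    b = len(xs) - a
    c = len(ys) - a
    d = len(uni) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    odds = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else 0.0)
    expected = len(xs) * len(ys) / len(uni)
    direction = "over" if a > expected else ("under" if a < expected else "none")
    return OverlapResult(name_x, name_y, len(xs), len(ys), a, len(uni),
                         float(odds), float(p), alternative, direction=direction)


def sets_by_clusters_heatmap(venn_sets: dict, clusters: pd.Series,
                             universe=None) -> pd.DataFrame:
    """Signed significance matrix for every (Venn set, cluster) intersection.

    Per cell, one-tailed Fisher tests for over- and under-representation are
    run; the smaller tail sets the direction, BH runs across all cells, and
    the entry is -log10(adjusted p) signed + for over, - for under.
    """
    if universe is None:
        universe = clusters.index
    uni = pd.Index(universe)
    labels = sorted(clusters.unique())
    records = []
    for sname, members in venn_sets.items():
        for cl in labels:
            cset = clusters.index[clusters == cl]
            over = fisher_overlap(members, cset, uni, "greater")
            under = fisher_overlap(members, cset, uni, "less")
            if over.p <= under.p:
                records.append((sname, cl, over.p, 1.0))
            else:
                records.append((sname, cl, under.p, -1.0))
    df = pd.DataFrame(records, columns=["set", "cluster", "p", "sign"])
    df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
    df["signed_score"] = df["sign"] * -np.log10(np.maximum(df["padj"], 1e-300))
    return df.pivot(index="set", columns="cluster", values="signed_score")


def ora_gmt(query, collection: dict, universe, fdr_max: float = 0.1
            ) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene list in every set
    of a GMT collection, BH-adjusted across the collection.

    Sets are intersected with the universe first; sets with empty
    intersection are reported with note='skipped' and excluded from BH.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    M, n = len(uni), len(q)
    rows = []
    for name, members in collection.items():
        s = set(members) & uni
        if not s:
            rows.append({"set": name, "set_size": 0, "overlap": 0,
                         "p": np.nan, "note": "skipped"})
            continue
        k = len(q & s)
        p = stats.hypergeom.sf(k - 1, M, len(s), n)
        rows.append({"set": name, "set_size": len(s), "overlap": k,
                     "p": float(p), "note": ""})
    df = pd.DataFrame(rows).set_index("set")
    ok = df["p"].notna()
    df["padj"] = np.nan
    if ok.any():
        df.loc[ok, "padj"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["significant"] = df["padj"] <= fdr_max
    return df


def external_overlap(flagged, external_genes, universe,
                     ortholog_map: pd.DataFrame | None = None,
                     name: str = "external") -> tuple[OverlapResult, dict]:
    """One-tailed (greater) Fisher overlap of a flagged gene set with an
    external list, optionally translated through a two-column ortholog map.

    Unmapped external identifiers are dropped and counted in the report.
    Raises if nothing maps into the universe.
    """
    external_genes = list(external_genes)
    report = {"n_external": len(external_genes), "n_dropped_unmapped": 0}
    if ortholog_map is not None:
        lut = dict(zip(ortholog_map.iloc[:, 0], ortholog_map.iloc[:, 1]))
        mapped = [lut[g] for g in external_genes if g in lut]
        report["n_dropped_unmapped"] = len(external_genes) - len(mapped)
        external_genes = mapped
    report["n_mapped"] = len(external_genes)
    in_universe = set(external_genes) & set(universe)
    report["n_in_universe"] = len(in_universe)
    if not in_universe:
        raise ValueError("no external identifiers map into the analysis universe")
    res = fisher_overlap(flagged, in_universe, universe, "greater",
                         name_x="flagged", name_y=name)
    return res, report


def read_gmt(path: str) -> dict[str, list[str]]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *members = parts
            members = [m for m in members if m]
            if not members:
                continue
            if name in sets:
                raise ValueError(f"duplicate set name in GMT: {name}")
            sets[name] = members
    return sets


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
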