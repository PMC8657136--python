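"""Profile clustering and the cluster characterization battery.

Selected genes are clustered on their mean log2(RPKM + pseudocount) profiles
across the 21 (genotype, dose) conditions with Euclidean distances and Ward
linkage, cut to k flat clusters. Each cluster is then characterized the way
the study's summary table does: regulation direction (top dose vs zero
dose), median expression, biotype composition (chi-squared enrichment vs the
non-regulated background), and gene length / TSS-to-E-box distance via a
resampling null that repeatedly draws equal-size sets of non-regulated
genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import GENOTYPES


def build_profile_matrix(rpkm: pd.DataFrame, design: pd.DataFrame,
                         genes, pseudocount: float = 1.0) -> pd.DataFrame:
    """Replicate-mean log2(RPKM + pseudocount), columns (genotype, dose)
    genotype-major with doses ascending."""
    genes = pd.Index(genes)
    missing = genes.difference(rpkm.index)
    if len(missing):
        raise KeyError(f"genes absent from the expression matrix: {list(missing)[:5]}")
    logr = np.log2(rpkm.loc[genes] + pseudocount)
    doses = sorted(design["dose"].unique())
    cols = {}
    for g in GENOTYPES:
        for d in doses:
            ids = design.loc[(design["genotype"] == g) & (design["dose"] == d),
                             "sample_id"]
            if len(ids):
                cols[(g, d)] = logr[ids].mean(axis=1)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["genotype", "dose"])
    return out


def hierarchical_cluster(profiles: pd.DataFrame, k: int = 12
                         ) -> tuple[pd.Series, np.ndarray]:
    """Ward/Euclidean agglomeration cut to exactly k clusters.

    Returns (gene -> label Series with labels 1..k renumbered by dendrogram
    leaf order, linkage matrix). Deterministic for a fixed row order.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of genes ({len(profiles)})")
    Z = hierarchy.linkage(profiles.to_numpy(), method="ward")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    relabel, nxt = {}, 1
    for leaf in order:
        lab = raw[leaf]
        if lab not in relabel:
            relabel[lab] = nxt
            nxt += 1
    labels = pd.Series([relabel[v] for v in raw], index=profiles.index,
                       name="cluster")
    return labels, Z


def dendrogram_newick(Z: np.ndarray, leaf_names) -> str:
    """Serialize a scipy linkage tree as Newick with branch lengths."""
    tree = hierarchy.to_tree(Z)
    names = list(leaf_names)
    # iterative post-order traversal to avoid recursion limits
    parts: dict[int, str] = {}
    stack = [(tree, False)]
    while stack:
        node, expanded = stack.pop()
        if node.is_leaf():
            parts[node.id] = names[node.id]
        elif not expanded:
            stack.append((node, True))
            stack.append((node.left, False))
            stack.append((node.right, False))
        else:
            ld = node.dist - node.left.dist
            rd = node.dist - node.right.dist
            parts[node.id] = (f"({parts[node.left.id]}:{ld:.6g},"
                              f"{parts[node.right.id]}:{rd:.6g})")
    return parts[tree.id] + ";"


def classify_direction(rpkm: pd.DataFrame, design: pd.DataFrame,
                       genotype: str = "WT",
                       low_dose: float | None = None,
                       high_dose: float | None = None) -> pd.Series:
    """Per gene: 'up' if replicate-mean RPKM at the top dose strictly exceeds
    the zero-dose mean, 'down' if strictly lower, else 'unchanged'."""
    doses = sorted(design["dose"].unique())
    low = doses[0] if low_dose is None else low_dose
    high = doses[-1] if high_dose is None else high_dose
    sel = design["genotype"] == genotype
    lo_ids = design.loc[sel & (design["dose"] == low), "sample_id"]
    hi_ids = design.loc[sel & (design["dose"] == high), "sample_id"]
    if not len(lo_ids) or not len(hi_ids):
        raise ValueError("endpoint doses missing for genotype " + genotype)
    lo = rpkm[lo_ids].mean(axis=1)
    hi = rpkm[hi_ids].mean(axis=1)
    return pd.Series(np.where(hi > lo, "up", np.where(hi < lo, "down",
                                                      "unchanged")),
                     index=rpkm.index, name="direction")


def resampling_median_test(cluster_values, background_values, B: int = 1000,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[float, float, str]:
    """Empirical two-sided test of the cluster median against medians of B
    equal-size draws (without replacement) from the background.

    p = min(1, 2 * min(r_low + 1, r_high + 1) / (B + 1)) where r_low / r_high
    count resampled medians <= / >= the observed one. Direction is 'less'
    when the observed median sits below the resampling distribution.
    """
    rng = np.random.default_rng() if rng is None else rng
    cl = np.asarray(cluster_values, dtype=float)
    bg = np.asarray(background_values, dtype=float)
    n = len(cl)
    if len(bg) < n:
        raise ValueError("background smaller than cluster")
    observed = float(np.median(cl))
    # vectorized without-replacement draws: argpartition of uniform keys
    keys = rng.random((B, len(bg)))
    idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
    meds = np.median(bg[idx], axis=1)
    r_low = int(np.sum(meds <= observed))
    r_high = int(np.sum(meds >= observed))
    p = min(1.0, 2.0 * min(r_low + 1, r_high + 1) / (B + 1))
    direction = "less" if r_low < r_high else "greater"
    return observed, p, direction


def categorical_enrichment_test(cluster_flags, background_flags
                                ) -> tuple[str, float, str]:
    """2x2 chi-squared (with continuity correction) of a binary attribute in
    the cluster vs the background; falls back to Fisher's exact test when an
    expected cell drops below 1. Returns (direction, p, method)."""
    cl = np.asarray(cluster_flags, dtype=bool)
    bg = np.asarray(background_flags, dtype=bool)
    table = np.array([[cl.sum(), (~cl).sum()], [bg.sum(), (~bg).sum()]])
    frac_cl = cl.mean() if len(cl) else 0.0
    frac_bg = bg.mean() if len(bg) else 0.0
    direction = "over" if frac_cl > frac_bg else ("under" if frac_cl < frac_bg
                                                  else "none")
    if table.sum() == 0 or table.sum(axis=0).min() == 0:
        return direction, 1.0, "degenerate"
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < 1:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return direction, float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return direction, float(p), "chi2"


def build_cluster_table(assignments: pd.Series, rpkm: pd.DataFrame,
                        design: pd.DataFrame, annotation: pd.DataFrame,
                        motif_distances: pd.DataFrame,
                        background_genes, B: int = 1000,
                        rng: np.random.Generator | None = None,
                        ebox_window: int = 1000,
                        categorical_alpha: float = 0.05,
                        resampling_alpha: float = 0.02) -> pd.DataFrame:
    """One characterization row per cluster.

    ``annotation`` needs gene_id, biotype, length_bp; ``motif_distances``
    needs gene_id, min_distance, ebox_within_1kb; ``background_genes`` are
    the non-regulated genes used for all enrichment/resampling comparisons.
    Adjusted p-values are BH across the k clusters within each statistic.
    """
    rng = np.random.default_rng() if rng is None else rng
    ann = annotation.set_index("gene_id")
    md = motif_distances.set_index("gene_id")
    bg = pd.Index(background_genes)
    direction = classify_direction(rpkm, design)
    mean_rpkm = rpkm.mean(axis=1)

    bg_noncoding = (ann.loc[bg, "biotype"] == "non_coding").to_numpy()
    bg_length = ann.loc[bg, "length_bp"].to_numpy(dtype=float)
    bg_ebox = md.loc[bg.intersection(md.index), "ebox_within_1kb"].to_numpy(dtype=bool)
    bg_dist = md.loc[bg.intersection(md.index), "min_distance"].dropna().to_numpy(dtype=float)

    rows = []
    for cl in sorted(assignments.unique()):
        genes = assignments.index[assignments == cl]
        dirs = direction.loc[genes]
        n = len(genes)
        pct_up = 100.0 * (dirs == "up").mean()
        pct_down = 100.0 * (dirs == "down").mean()
        noncoding = (ann.loc[genes, "biotype"] == "non_coding").to_numpy()
        nc_dir, nc_p, nc_method = categorical_enrichment_test(noncoding, bg_noncoding)
        ebox = md.loc[genes.intersection(md.index), "ebox_within_1kb"].to_numpy(dtype=bool)
        eb_dir, eb_p, eb_method = categorical_enrichment_test(ebox, bg_ebox)
        med_len, len_p, len_dir = resampling_median_test(
            ann.loc[genes, "length_bp"].to_numpy(dtype=float), bg_length, B, rng)
        dists = md.loc[genes.intersection(md.index), "min_distance"].dropna().to_numpy(dtype=float)
        if len(dists) and len(bg_dist) >= len(dists):
            med_dist, dist_p, dist_dir = resampling_median_test(dists, bg_dist, B, rng)
        else:
            med_dist, dist_p, dist_dir = np.nan, np.nan, "none"
        rows.append({
            "cluster": cl, "n_genes": n,
            "overall_pattern": "up" if pct_up > 50 else ("down" if pct_down > 50 else "mixed"),
            "pct_up": pct_up, "pct_down": pct_down,
            "pct_unchanged": 100.0 - pct_up - pct_down,
            "median_rpkm": float(mean_rpkm.loc[genes].median()),
            "pct_noncoding": 100.0 * noncoding.mean(),
            "noncoding_direction": nc_dir, "noncoding_p": nc_p,
            "noncoding_method": nc_method,
            "median_gene_length_bp": med_len, "length_p": len_p,
            "length_direction": len_dir,
            "pct_with_ebox_1kb": 100.0 * ebox.mean() if len(ebox) else np.nan,
            "ebox_direction": eb_dir, "ebox_p": eb_p, "ebox_method": eb_method,
            "median_min_tss_ebox_bp": med_dist, "tss_ebox_p": dist_p,
            "tss_ebox_direction": dist_dir,
        })
    table = pd.DataFrame(rows).set_index("cluster")
    for col, alpha in (("noncoding_p", categorical_alpha),
                       ("ebox_p", categorical_alpha),
                       ("length_p", resampling_alpha),
                       ("tss_ebox_p", resampling_alpha)):
        adj = np.full(len(table), np.nan)
        ok = table[col].notna().to_numpy()
        if ok.any():
            adj[ok] = multipletests(table[col].to_numpy()[ok], method="fdr_bh")[1]
        stem = col[:-2]
        table[stem + "_padj"] = adj
        table[stem + "_significant"] = adj < alpha
    return table
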