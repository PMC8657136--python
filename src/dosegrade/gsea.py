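"""MYC-level sensitivity scoring and preranked gene-set enrichment.

A gene's sensitivity to the inducer in one genotype is the ratio of its
low-dose fold change (25 vs 0 ng/mL) to its high-dose fold change (600 vs
300 ng/mL), computed on replicate-mean RPKM with a pseudocount:
s = FC_25/0 / FC_600/300. Genes responding mostly at low doses have s >> 1.
The ranking statistic contrasts the two mutants, rank = log2(s_T58A /
s_T58I); the log is order-preserving relative to the raw ratio and keeps the
weighting symmetric.

The preranked GSEA is a weighted Kolmogorov-Smirnov running sum: walking the
ranked list, set members add |metric|^p normalized by the set total, misses
subtract 1/(N - n_set); the enrichment score is the maximum-magnitude
deviation. Significance comes from gene-label permutations: null same-size
sets, sign-matched NES normalization, permutation p with the (r+1)/(m+1)
estimator and BH adjustment across sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

SENSITIVITY_LOW = (25.0, 0.0)
SENSITIVITY_HIGH = (600.0, 300.0)


def _replicate_mean(rpkm: pd.DataFrame, design: pd.DataFrame, genotype: str,
                    dose: float) -> pd.Series:
    ids = design.loc[(design["genotype"] == genotype) & (design["dose"] == dose),
                     "sample_id"]
    if not len(ids):
        raise ValueError(f"genotype {genotype} is missing dose {dose}")
    return rpkm[ids].mean(axis=1)


def sensitivity_scores(rpkm: pd.DataFrame, design: pd.DataFrame,
                       pseudocount: float = 0.125,
                       genotypes=("WT", "T58A", "T58I")) -> pd.DataFrame:
    """Per-gene sensitivity table and the T58A/T58I ranking metric.

    fc_low = (mean RPKM at 25 + pc) / (mean RPKM at 0 + pc); fc_high likewise
    for 600 vs 300; s = fc_low / fc_high; rank_metric = log2(s_T58A/s_T58I).
    """
    out = pd.DataFrame(index=rpkm.index)
    for g in genotypes:
        lo_n = _replicate_mean(rpkm, design, g, SENSITIVITY_LOW[0]) + pseudocount
        lo_d = _replicate_mean(rpkm, design, g, SENSITIVITY_LOW[1]) + pseudocount
        hi_n = _replicate_mean(rpkm, design, g, SENSITIVITY_HIGH[0]) + pseudocount
        hi_d = _replicate_mean(rpkm, design, g, SENSITIVITY_HIGH[1]) + pseudocount
        fc_low = lo_n / lo_d
        fc_high = hi_n / hi_d
        out[f"fc_low_{g}"] = fc_low
        out[f"fc_high_{g}"] = fc_high
        # sensitivity on fold-change magnitudes, so a strongly down-regulated
        # low-dose responder scores just as sensitive as an up-regulated one
        out[f"s_{g}"] = np.maximum(fc_low, 1.0 / fc_low) / np.maximum(
            fc_high, 1.0 / fc_high)
    out["rank_metric"] = np.log2(out["s_T58A"] / out["s_T58I"])
    return out


def rank_genes(metric: pd.Series) -> pd.Series:
    """Descending metric order, ties broken by ascending gene identifier."""
    df = pd.DataFrame({"metric": metric})
    df["gene"] = df.index
    df = df.sort_values(["metric", "gene"], ascending=[False, True])
    return pd.Series(df["metric"].to_numpy(), index=df["gene"].to_numpy())


def enrichment_score(metric_sorted: np.ndarray, hit_idx: np.ndarray,
                     p: float = 1.0) -> tuple[float, int]:
    """ES of a set with (sorted, 0-based) hit positions in a ranked list.

    Returns (ES, extremum hit rank): for positive ES the index into hit_idx
    where the running sum peaks; for negative ES the hit at/after the trough.
    Running-sum extrema occur at hit positions (peaks) and immediately before
    hits (troughs), so only those candidates are evaluated.
    """
    N = len(metric_sorted)
    k = len(hit_idx)
    if k == 0 or k >= N:
        raise ValueError("set must be non-empty and smaller than the universe")
    w = np.abs(metric_sorted[hit_idx]) ** p
    nr = w.sum()
    if nr == 0:  # all-zero weights: fall back to unweighted steps
        w = np.ones(k)
        nr = float(k)
    cum = np.cumsum(w) / nr
    j = np.arange(k)
    miss = 1.0 / (N - k)
    at_hit = cum - (hit_idx - j) * miss            # value just after each hit
    before_hit = np.concatenate(([0.0], cum[:-1])) - (hit_idx - j) * miss
    pos_i = int(np.argmax(at_hit))
    neg_i = int(np.argmin(before_hit))
    pos, neg = at_hit[pos_i], before_hit[neg_i]
    if pos + neg > 1e-12:
        return float(pos), pos_i
    if pos + neg < -1e-12:
        return float(neg), neg_i
    # magnitude tie (to float tolerance): take the extremum reached first
    # along the walk, matching a hand-stepped running sum (a peak sits at its
    # hit, a trough one position before its hit)
    if hit_idx[pos_i] <= hit_idx[neg_i] - 1:
        return float(pos), pos_i
    return float(neg), neg_i


def _null_es(metric_sorted: np.ndarray, k: int, n_perm: int,
             rng: np.random.Generator, p: float = 1.0) -> np.ndarray:
    """Null ES for random same-size gene sets (gene-label permutation)."""
    N = len(metric_sorted)
    keys = rng.random((n_perm, N))
    idx = np.sort(np.argpartition(keys, k - 1, axis=1)[:, :k], axis=1)
    w = np.abs(metric_sorted[idx]) ** p
    nr = w.sum(axis=1, keepdims=True)
    nr = np.where(nr == 0, k, nr)
    cum = np.cumsum(w, axis=1) / nr
    j = np.arange(k)[None, :]
    miss = 1.0 / (N - k)
    at_hit = cum - (idx - j) * miss
    before_hit = np.concatenate(
        [np.zeros((n_perm, 1)), cum[:, :-1]], axis=1) - (idx - j) * miss
    pos = at_hit.max(axis=1)
    neg = before_hit.min(axis=1)
    return np.where(pos >= -neg, pos, neg)


def gsea_preranked(metric: pd.Series, collection: dict, n_perm: int = 1000,
                   weight: float = 1.0, min_size: int = 2,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None) -> pd.DataFrame:
    """Preranked GSEA over a GMT-style collection.

    Per set: ES, sign-matched NES (ES divided by the mean |null ES| of the
    same sign), permutation p = (r+1)/(m+1) within the same-sign null, BH
    adjustment across sets, and the leading edge (members at or before the
    positive extremum; at or after the negative one).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if not np.all(np.isfinite(metric.to_numpy(dtype=float))):
        raise ValueError("ranking metric must be finite for all genes")
    ranked = rank_genes(metric)
    genes = ranked.index.to_numpy()
    vals = ranked.to_numpy(dtype=float)
    pos_of = {g: i for i, g in enumerate(genes)}
    N = len(genes)

    rows = []
    for name, members in collection.items():
        hit_idx = np.sort(np.array([pos_of[g] for g in set(members) if g in pos_of],
                                   dtype=int))
        k = len(hit_idx)
        if k < min_size or k >= N:
            continue
        es, ext = enrichment_score(vals, hit_idx, weight)
        null = _null_es(vals, k, n_perm, rng, weight)
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same):
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else np.nan
            r = int(np.sum(np.abs(same) >= abs(es)))
            p_perm = (r + 1) / (len(same) + 1)
        else:
            nes, p_perm = np.nan, 1.0
        if es >= 0:
            le = [genes[i] for i in hit_idx[:ext + 1]]
        else:
            le = [genes[i] for i in hit_idx[ext:]]
        rows.append({"set": name, "size": k, "ES": es, "NES": nes,
                     "p_perm": p_perm, "leading_edge": le})
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = multipletests(df["p_perm"], method="fdr_bh")[1]
    else:
        df["padj"] = []
    return df.set_index("set") if len(df) else df


def select_enriched(results: pd.DataFrame, padj_max: float = 0.05,
                    abs_nes_min: float = 1.7) -> pd.DataFrame:
    """Significant sets: adjusted p <= padj_max and |NES| >= abs_nes_min,
    both inclusive."""
    if not len(results):
        return results
    keep = (results["padj"] <= padj_max) & (results["NES"].abs() >= abs_nes_min)
    return results.loc[keep.fillna(False)]
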