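"""Dose-response differential expression for the genotype x dose factorial.

The model is a per-gene negative-binomial log-linear GLM with one mean per
(genotype, dose) cell and a log library-size offset. Three quasi-likelihood
F-tests are computed per gene:

* ``wt``    -- dose effect in WT (reduced model: WT means collapsed, 6 df);
* ``t58a``  -- T58A dose profile differs from WT beyond an intercept shift
  (reduced model: mutant profile = WT profile + shift, 6 df);
* ``t58i``  -- same for T58I.

Gene-wise NB dispersions are estimated by Cox-Reid adjusted profile
likelihood on the full factorial fit, moderated toward a lowess
mean-dispersion trend. The QL F-statistic divides the per-df deviance drop
by an empirical-Bayes "squeezed" residual deviance scale (limma-style
moments estimator of the scale prior). Benjamini-Hochberg adjustment is
applied within each test family; the selection rule flags genes with
q < 0.01 and a >= 2-fold change between at least two fitted condition means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .synthetic import GENOTYPES, MUTANTS

PSEUDOCOUNT_CPM = 0.125  # floor for fitted means when computing fold changes


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def compute_cpm(counts: pd.DataFrame, library_sizes: pd.Series | None = None
                ) -> pd.DataFrame:
    """Counts per million; library sizes default to column sums."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts / library_sizes * 1e6


def compute_rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
                 library_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (libsize * length_bp).

    Genes without a length are dropped with a warning.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    lengths = gene_lengths.reindex(counts.index)
    missing = lengths.isna() | (lengths <= 0)
    if missing.any():
        import warnings
        warnings.warn(f"dropping {int(missing.sum())} genes without a valid length")
    kept = counts.loc[~missing]
    lengths = lengths.loc[~missing].astype(float)
    return kept.mul(1e9, axis=0).div(library_sizes, axis=1).div(lengths, axis=0)


def median_ratio_library_sizes(counts: pd.DataFrame) -> pd.Series:
    """Composition-corrected effective library sizes (median-of-ratios).

    Per sample, the median across genes of count / geometric-mean count,
    rescaled to the total of the raw column sums. Robust to a minority of
    strongly regulated genes shifting the column sums (composition bias);
    optional alternative to plain column-sum scaling.
    """
    logc = np.log(counts.where(counts > 0))
    ref = logc.mean(axis=1)
    ok = ref.notna()
    ratios = logc.loc[ok].sub(ref.loc[ok], axis=0)
    factors = np.exp(ratios.median(axis=0))
    raw = counts.sum(axis=0)
    sizes = factors / factors.mean() * raw.mean()
    return pd.Series(sizes, index=counts.columns, name="library_size")


def filter_genes(cpm: pd.DataFrame, min_cpm: float = 0.95,
                 min_samples: int = 3) -> pd.Index:
    """Retain genes with CPM >= min_cpm in at least min_samples samples
    (both thresholds inclusive)."""
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return cpm.index[keep]


# ---------------------------------------------------------------------------
# NB likelihood primitives (vectorized over genes)
# ---------------------------------------------------------------------------

def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Elementwise NB unit deviance, safe at y=0 and mu=0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-300)
    alpha = np.maximum(alpha, 1e-12)
    t1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    t2 = (y + 1.0 / alpha) * (np.log1p(alpha * y) - np.log1p(alpha * mu))
    return 2.0 * (t1 - t2)


def nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB log-likelihood summed over the last axis."""
    alpha = np.maximum(alpha, 1e-12)
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-300)
    ll = (special.gammaln(y + r) - special.gammaln(r) - special.gammaln(y + 1)
          + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)))
    return ll.sum(axis=-1)


def _fit_group_mean(y: np.ndarray, libsizes: np.ndarray, alpha: np.ndarray,
                    n_iter: int = 30) -> np.ndarray:
    """MLE of a single per-unit-library mean for one sample group.

    y: (G, S_group); libsizes: (S_group,); alpha: (G,) or (G,1).
    Newton iterations on b = log(mean); groups with all-zero counts get 0.
    """
    y = np.asarray(y, dtype=float)
    alpha = np.asarray(alpha, dtype=float).reshape(-1, 1)
    sumy = y.sum(axis=1)
    sumN = libsizes.sum()
    b = np.log(np.maximum(sumy, 0.1) / sumN)
    for _ in range(n_iter):
        mu = np.exp(b)[:, None] * libsizes[None, :]
        denom = 1.0 + alpha * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = np.maximum((mu / denom).sum(axis=1), 1e-12)
        step = np.clip(score / info, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < 1e-12:
            break
    m = np.exp(b)
    return np.where(sumy == 0, 0.0, m)


def _cells(design: pd.DataFrame, doses: list[float]) -> list[tuple[str, float, np.ndarray]]:
    """(genotype, dose, sample index array) per factorial cell, genotype-major."""
    out = []
    for g in GENOTYPES:
        for d in doses:
            idx = np.flatnonzero((design["genotype"] == g).to_numpy()
                                 & (design["dose"] == d).to_numpy())
            out.append((g, d, idx))
    return out


def fit_cell_means(counts: np.ndarray, libsizes: np.ndarray,
                   cells: list, alpha: np.ndarray) -> np.ndarray:
    """Saturated factorial fit: (G, n_cells) per-unit-library means."""
    means = np.empty((counts.shape[0], len(cells)))
    for c, (_, _, idx) in enumerate(cells):
        means[:, c] = _fit_group_mean(counts[:, idx], libsizes[idx], alpha)
    return means


def _cells_deviance(counts: np.ndarray, libsizes: np.ndarray, cells: list,
                    means: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """(G, n_cells) deviance contributions of each saturated cell."""
    G = counts.shape[0]
    dev = np.empty((G, len(cells)))
    a = alpha[:, None]
    for c, (_, _, idx) in enumerate(cells):
        mu = means[:, c][:, None] * libsizes[idx][None, :]
        dev[:, c] = nb_deviance(counts[:, idx], mu, a).sum(axis=1)
    return dev


def fit_shift_model(counts: np.ndarray, offsets: np.ndarray, X: np.ndarray,
                    alpha: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene NB IRLS for an arbitrary design matrix with offsets.

    counts: (G, S); offsets: (S,) log library sizes; X: (S, P).
    Returns (deviance (G,), converged (G,) bool). Convergence criterion:
    relative deviance change < tol or max_iter iterations.
    """
    G, S = counts.shape
    P = X.shape[1]
    dev_out = np.empty(G)
    conv = np.zeros(G, dtype=bool)
    ridge = 1e-8 * np.eye(P)
    for g in range(G):
        y = counts[g].astype(float)
        a = max(alpha[g], 1e-12)
        eta0 = np.log(np.maximum(y, 0.5)) - offsets
        beta, *_ = np.linalg.lstsq(X, eta0, rcond=None)
        dev_prev = np.inf
        for _ in range(max_iter):
            eta = np.clip(X @ beta + offsets, -30.0, 30.0)
            mu = np.exp(eta)
            w = mu / (1.0 + a * mu)
            z = (eta - offsets) + (y - mu) / mu
            Xw = X * w[:, None]
            beta = np.linalg.solve(X.T @ Xw + ridge, Xw.T @ z)
            dev = float(nb_deviance(y, np.exp(np.clip(X @ beta + offsets, -30, 30)),
                                    np.array(a)).sum())
            if np.isfinite(dev_prev) and abs(dev_prev - dev) < tol * (abs(dev) + 1.0):
                conv[g] = True
                break
            dev_prev = dev
        dev_out[g] = dev
    return dev_out, conv


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def estimate_dispersion(counts: pd.DataFrame, design: pd.DataFrame,
                        library_sizes: pd.Series | None = None,
                        trend_weight: float = 1.0,
                        grid: tuple[float, float, int] = (1e-6, 5.0, 40),
                        ) -> pd.DataFrame:
    """Gene-wise NB dispersion by Cox-Reid adjusted profile likelihood on the
    full genotype x dose factorial, moderated toward a lowess trend on
    average log-CPM.

    Returns a DataFrame with columns ``genewise``, ``trend``, ``moderated``.
    ``trend_weight`` in [0, 1] is the shrinkage toward the trend on the log
    scale (0 = pure gene-wise, 1 = pure trend).
    """
    reps = design.groupby(["genotype", "dose"]).size()
    if (reps < 2).all():
        raise ValueError(
            "single replicate per condition: gene-wise dispersion is not "
            "identifiable; rerun with a common-dispersion fallback "
            "(common_dispersion)")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    y = counts.to_numpy(dtype=float)
    ls = library_sizes.to_numpy(dtype=float)
    doses = sorted(design["dose"].unique())
    cells = _cells(design, doses)
    G = y.shape[0]

    lo, hi, n_grid = grid
    alphas = np.exp(np.linspace(np.log(lo), np.log(hi), int(n_grid)))
    apl = np.empty((G, len(alphas)))
    for k, a in enumerate(alphas):
        av = np.full(G, a)
        means = fit_cell_means(y, ls, cells, av)
        mu = np.empty_like(y)
        cr = np.zeros(G)
        for c, (_, _, idx) in enumerate(cells):
            mu_c = means[:, c][:, None] * ls[idx][None, :]
            mu[:, idx] = mu_c
            w = mu_c / (1.0 + a * mu_c)
            cr += np.log(np.maximum(w.sum(axis=1), 1e-300))
        apl[:, k] = nb_loglik(y, mu, av[:, None]) - 0.5 * cr

    best = np.argmax(apl, axis=1)
    genewise = alphas[best]
    # quadratic refinement in log-alpha for interior maxima
    interior = (best > 0) & (best < len(alphas) - 1)
    if interior.any():
        i = best[interior]
        la = np.log(alphas)
        y0, y1, y2 = (apl[interior, i - 1], apl[interior, i], apl[interior, i + 1])
        denom = (y0 - 2 * y1 + y2)
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (y0 - y2) / denom, 0.0)
        step = la[1] - la[0]
        genewise = genewise.copy()
        genewise[interior] = np.exp(la[i] + np.clip(shift, -1, 1) * step)

    ave_logcpm = np.log2(compute_cpm(counts, library_sizes).mean(axis=1) + 0.125)
    order = np.argsort(ave_logcpm.to_numpy())
    sm = lowess(np.log(genewise)[order], ave_logcpm.to_numpy()[order],
                frac=0.4, return_sorted=False)
    trend = np.empty(G)
    trend[order] = np.exp(sm)
    moderated = np.exp((1 - trend_weight) * np.log(genewise)
                       + trend_weight * np.log(trend))
    return pd.DataFrame({"genewise": genewise, "trend": trend,
                         "moderated": np.maximum(moderated, 0.0)},
                        index=counts.index)


def common_dispersion(counts: pd.DataFrame, design: pd.DataFrame,
                      library_sizes: pd.Series | None = None) -> float:
    """Single pooled dispersion (fallback when replication is minimal)."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    y = counts.to_numpy(dtype=float)
    ls = library_sizes.to_numpy(dtype=float)
    doses = sorted(design["dose"].unique())
    cells = _cells(design, doses)
    alphas = np.exp(np.linspace(np.log(1e-6), np.log(5.0), 40))
    ll = []
    for a in alphas:
        av = np.full(y.shape[0], a)
        means = fit_cell_means(y, ls, cells, av)
        mu = np.empty_like(y)
        for c, (_, _, idx) in enumerate(cells):
            mu[:, idx] = means[:, c][:, None] * ls[idx][None, :]
        ll.append(nb_loglik(y, mu, av[:, None]).sum())
    return float(alphas[int(np.argmax(ll))])


# ---------------------------------------------------------------------------
# empirical-Bayes scale squeeze (limma-style)
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    f = lambda x: special.polygamma(1, x) - y
    from scipy.optimize import brentq
    return brentq(f, 1e-6, 1e8)


def squeeze_var(s2: np.ndarray, df: float, covariate: np.ndarray | None = None
                ) -> tuple[np.ndarray, float, np.ndarray]:
    """Moderate per-gene variances toward an empirical-Bayes prior.

    Fits a scaled F prior s2 ~ s0^2 F(df, d0) by matching moments of
    log(s2). When ``covariate`` (average log-CPM) is given the prior
    location s0 is a lowess trend on it rather than a constant, so genes are
    shrunk toward level-matched scales. Returns (posterior variances, d0,
    prior variances); d0 is capped at 1e6 for downstream F quantiles.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-10)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is None:
        loc = np.full_like(e, float(np.mean(e)))
    else:
        order = np.argsort(covariate)
        sm = lowess(e[order], covariate[order], frac=0.4, return_sorted=False)
        loc = np.empty_like(e)
        loc[order] = sm
    evar = float(np.var(e - loc, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, 1e6)
        s0 = np.exp(loc + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = 1e6
        s0 = np.exp(loc)
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, float(d0), s0


# ---------------------------------------------------------------------------
# full per-gene analysis
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Container for the per-gene model results.

    ``results`` has one row per analysed gene: dispersion, per-family p/q,
    per-family max |log2 FC| over fitted condition means, convergence flags
    and the three selection flags once :func:`select_models` has run.
    ``fitted_cpm`` holds fitted means on the CPM scale, columns MultiIndex
    (genotype, dose).
    """
    results: pd.DataFrame
    fitted_cpm: pd.DataFrame
    filtered_genes: pd.Index
    d0: float
    s0: float
    doses: list[float]


def _max_abs_log2fc(fitted_cpm: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """max |log2 ratio| over the given columns, means floored at the CPM
    pseudocount."""
    sub = np.maximum(fitted_cpm[:, cols], PSEUDOCOUNT_CPM)
    return np.log2(sub.max(axis=1) / sub.min(axis=1))


def fit_gene_models(counts: pd.DataFrame, design: pd.DataFrame,
                    library_sizes: pd.Series | None = None,
                    dispersion: pd.Series | None = None,
                    trend_weight: float = 1.0) -> DEResult:
    """Fit full and reduced NB models for every gene and compute the three
    QL F-tests with BH adjustment per family.

    ``counts`` should already be filtered (see :func:`filter_genes`);
    ``dispersion`` overrides the internal moderated estimate.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    design = design.reset_index(drop=True)
    if list(design["sample_id"]) != list(counts.columns):
        design = design.set_index("sample_id").loc[counts.columns].reset_index()
    y = counts.to_numpy(dtype=float)
    ls = library_sizes.reindex(counts.columns).to_numpy(dtype=float)
    offsets = np.log(ls)
    doses = sorted(design["dose"].unique())
    n_doses = len(doses)
    cells = _cells(design, doses)
    G, S = y.shape

    if dispersion is None:
        disp_tab = estimate_dispersion(counts, design, library_sizes,
                                       trend_weight=trend_weight)
        alpha = disp_tab["moderated"].to_numpy()
    elif isinstance(dispersion, pd.Series):
        alpha = dispersion.reindex(counts.index).to_numpy(dtype=float)
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (G,)).copy()

    means = fit_cell_means(y, ls, cells, alpha)
    cell_dev = _cells_deviance(y, ls, cells, means, alpha)
    full_dev = cell_dev.sum(axis=1)
    resid_df = S - len(cells)

    geno_of_cell = np.array([g for g, _, _ in cells])
    wt_cols = np.flatnonzero(geno_of_cell == "WT")

    # WT family: collapse WT doses to one mean
    wt_idx = np.flatnonzero((design["genotype"] == "WT").to_numpy())
    m_wt_flat = _fit_group_mean(y[:, wt_idx], ls[wt_idx], alpha)
    dev_wt_red = nb_deviance(
        y[:, wt_idx], m_wt_flat[:, None] * ls[wt_idx][None, :],
        alpha[:, None]).sum(axis=1)
    delta = {"wt": dev_wt_red - cell_dev[:, wt_cols].sum(axis=1)}
    converged = {"wt": np.ones(G, dtype=bool)}

    # mutant families: mutant profile constrained to WT shape + intercept
    dose_of_sample = design["dose"].to_numpy()
    geno_of_sample = design["genotype"].to_numpy()
    for mut in MUTANTS:
        fam_idx = np.flatnonzero((geno_of_sample == "WT") | (geno_of_sample == mut))
        Xd = np.zeros((len(fam_idx), n_doses + 1))
        for j, s in enumerate(fam_idx):
            Xd[j, doses.index(dose_of_sample[s])] = 1.0
            if geno_of_sample[s] == mut:
                Xd[j, n_doses] = 1.0
        dev_red, conv = fit_shift_model(y[:, fam_idx], offsets[fam_idx], Xd, alpha)
        mut_cols = np.flatnonzero((geno_of_cell == "WT") | (geno_of_cell == mut))
        key = mut.lower()
        delta[key] = dev_red - cell_dev[:, mut_cols].sum(axis=1)
        converged[key] = conv

    s2 = full_dev / resid_df
    ave_logcpm = np.log2(y.mean(axis=1) / ls.mean() * 1e6 + PSEUDOCOUNT_CPM)
    s2_post, d0, s0 = squeeze_var(s2, resid_df, covariate=ave_logcpm)

    ddf = n_doses - 1
    results = pd.DataFrame(index=counts.index)
    results["dispersion"] = alpha
    fitted_cpm = means * 1e6
    for key in ("wt", "t58a", "t58i"):
        d = np.maximum(delta[key], 0.0)
        F = (d / ddf) / s2_post
        p = stats.f.sf(F, ddf, d0 + resid_df)
        p = np.where(converged[key], p, np.nan)
        q = np.full(G, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        results[f"f_{key}"] = F
        results[f"p_{key}"] = p
        results[f"q_{key}"] = q
        results[f"converged_{key}"] = converged[key]
    results["delta_dev_wt"] = delta["wt"]

    geno_cols = {g: np.flatnonzero(geno_of_cell == g) for g in GENOTYPES}
    results["maxlfc_wt"] = _max_abs_log2fc(fitted_cpm, geno_cols["WT"])
    for mut in MUTANTS:
        cols = np.concatenate([geno_cols["WT"], geno_cols[mut]])
        results[f"maxlfc_{mut.lower()}"] = _max_abs_log2fc(fitted_cpm, cols)
    results["max_abs_log2fc"] = _max_abs_log2fc(
        fitted_cpm, np.arange(fitted_cpm.shape[1]))

    columns = pd.MultiIndex.from_tuples([(g, d) for g, d, _ in cells],
                                        names=["genotype", "dose"])
    fitted = pd.DataFrame(fitted_cpm, index=counts.index, columns=columns)
    return DEResult(results, fitted, counts.index, d0, s0, doses)


def select_models(result: DEResult, q_max: float = 0.01,
                  min_fold: float = 2.0) -> pd.DataFrame:
    """Selection flags: q(family) < q_max and max fitted fold change >= min_fold
    over the family's condition pairs (WT dose pairs for the WT family;
    all {WT, mutant} x dose pairs for a mutant family)."""
    res = result.results
    min_lfc = np.log2(min_fold)
    flags = pd.DataFrame(index=res.index)
    flags["regulated_wt"] = (res["q_wt"] < q_max) & (res["maxlfc_wt"] >= min_lfc)
    flags["diff_t58a"] = (res["q_t58a"] < q_max) & (res["maxlfc_t58a"] >= min_lfc)
    flags["diff_t58i"] = (res["q_t58i"] < q_max) & (res["maxlfc_t58i"] >= min_lfc)
    for c in flags:
        flags[c] = flags[c].fillna(False)
    result.results = res.join(flags)
    return flags


def run_de(counts: pd.DataFrame, design: pd.DataFrame,
           gene_lengths: pd.Series | None = None,
           library_sizes: pd.Series | None = None,
           min_cpm: float = 0.95, min_samples: int = 3,
           q_max: float = 0.01, min_fold: float = 2.0,
           dispersion: pd.Series | None = None,
           normalization: str = "median_ratio") -> DEResult:
    """Filter, fit, test and select in one call.

    ``normalization`` chooses the model offsets: composition-corrected
    median-of-ratios effective sizes ("median_ratio", default -- robust when
    regulation is not balanced between up and down) or plain column sums
    ("column_sum").
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    cpm = compute_cpm(counts, library_sizes)
    kept = filter_genes(cpm, min_cpm=min_cpm, min_samples=min_samples)
    if normalization == "median_ratio":
        model_sizes = median_ratio_library_sizes(counts.loc[kept])
    elif normalization == "column_sum":
        model_sizes = library_sizes
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")
    result = fit_gene_models(counts.loc[kept], design, model_sizes,
                             dispersion=dispersion)
    select_models(result, q_max=q_max, min_fold=min_fold)
    return result
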