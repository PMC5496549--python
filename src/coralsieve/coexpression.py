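"""Unsigned weighted coexpression networks from raw count matrices.

Pipeline: low-coverage filter (mean count >= 1) -> median-of-ratios
size-factor normalization -> log2(x+1) expression -> unsigned adjacency
|cor|^power -> topological overlap -> average-linkage clustering with a
static cut -> eigengene-correlation merging -> single-outlier module
filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNASSIGNED = 0


def filter_low_coverage(counts: pd.DataFrame, min_mean: float = 1.0) -> pd.DataFrame:
    """Drop genes whose mean count across samples is strictly below
    ``min_mean`` (default 1)."""
    kept = counts[counts.mean(axis=1) >= min_mean]
    if kept.empty:
        raise ValueError("no genes pass the low-coverage filter")
    logger.info("low-coverage filter: kept %d / %d genes", len(kept), len(counts))
    return kept


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with nonzero counts in every sample, compute each gene's
    geometric mean across samples; a sample's factor is the median over
    those genes of count / geometric mean.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; apply a coverage "
            "pre-filter or supply deeper data"
        )
    ref = mat[all_nonzero]
    geo_mean = np.exp(np.mean(np.log(ref), axis=1))
    ratios = ref / geo_mean[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def median_ratio_normalize(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Return (size factors, counts divided by per-sample factors)."""
    factors = median_ratio_size_factors(counts)
    return factors, counts / factors


def log_expression(normalized: pd.DataFrame) -> pd.DataFrame:
    """log2(normalized count + 1), the default network input."""
    return np.log2(normalized + 1.0)


def _drop_constant_genes(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"removed {int(constant.sum())} constant genes")
        expr = expr[~constant]
    return expr


def _abs_corr(expr: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(expr)
    np.fill_diagonal(c, 1.0)
    return np.abs(np.nan_to_num(c))


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log regression of degree frequency on binned
    connectivity (the scale-free topology criterion)."""
    k = connectivity[connectivity > 0]
    if len(k) < n_bins or np.ptp(k) == 0:
        return 0.0
    # equal-width bins over the connectivity range; frequency per bin
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    centers = np.array(
        [k[idx == b].mean() if freq[b] else np.nan for b in range(n_bins)]
    )
    ok = (freq > 0) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(freq[ok] / freq.sum())
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    powers: tuple = tuple(range(1, 21)),
    r2_cut: float = 0.8,
    default_power: int = 4,
) -> tuple[pd.DataFrame, int]:
    """Scale-free fit table over candidate powers and the chosen power.

    Chosen = smallest power reaching ``r2_cut``; falls back to
    ``default_power`` when none does.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    expr = _drop_constant_genes(expr)
    corr = _abs_corr(expr.to_numpy(dtype=float))
    rows = []
    chosen = None
    for beta in powers:
        adj = corr**beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        r2 = scale_free_fit(k)
        rows.append({"power": beta, "scale_free_r2": r2, "mean_connectivity": k.mean()})
        if chosen is None and r2 >= r2_cut:
            chosen = beta
    if chosen is None:
        chosen = default_power
        logger.info("no power reached R^2 >= %.2f; using default %d", r2_cut, chosen)
    return pd.DataFrame(rows), chosen


def adjacency_matrix(expr: pd.DataFrame, power: float) -> np.ndarray:
    if power <= 0:
        raise ValueError("power must be positive")
    adj = _abs_corr(expr.to_numpy(dtype=float)) ** power
    np.fill_diagonal(adj, 1.0)
    return adj


def topological_overlap(adjacency: np.ndarray, block_size: int = 2000) -> np.ndarray:
    """TOM similarity from an unsigned adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    diagonal set to 1.  Computed in row blocks to bound memory.
    """
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    a_off = a.copy()
    np.fill_diagonal(a_off, 0.0)
    k = a_off.sum(axis=1)
    tom = np.empty_like(a)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = a_off[start:stop]
        # zero diagonal makes the u=i and u=j terms of the sum vanish,
        # so the plain product already equals l_ij
        l = block @ a_off
        denom = np.minimum(k[start:stop, None], k[None, :]) + 1.0 - block
        tom[start:stop] = (l + block) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


@dataclass
class ModuleSet:
    labels: pd.Series  # gene -> module label, 0 = unassigned
    eigengenes: pd.DataFrame  # module x sample
    variance_explained: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return [m for m in sorted(self.labels.unique()) if m != UNASSIGNED]

    def genes_in(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def module_eigengenes(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, dict]:
    """First principal component of each module's standardized expression.

    Genes are standardized across samples; the eigengene is the first
    right-singular vector over samples, unit norm, sign-oriented so it
    correlates non-negatively with the module's mean standardized
    expression.  Returns (module x sample eigengene frame,
    variance-explained per module).
    """
    mods = [m for m in sorted(labels.unique()) if m != UNASSIGNED]
    rows = {}
    var_explained = {}
    for m in mods:
        genes = labels.index[labels == m]
        sub = expr.loc[genes].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (sub - mu) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pc1 = vt[0]
        var_explained[m] = float(s[0] ** 2 / np.sum(s**2))
        mean_profile = z.mean(axis=0)
        if np.dot(pc1, mean_profile) < 0:
            pc1 = -pc1
        rows[m] = pc1
    eg = pd.DataFrame(rows, index=expr.columns).T
    eg.index.name = "module"
    return eg, var_explained


def cluster_modules(
    expr: pd.DataFrame,
    tom: np.ndarray,
    min_size: int = 30,
    cut_height_frac: float = 0.99,
    merge_cut: float = 0.3,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static cut, size
    floor, and iterative eigengene-correlation merging.

    Modules whose eigengenes correlate above ``1 - merge_cut`` are
    merged (most-correlated pair first), recomputing eigengenes after
    each merge.  Genes in clusters below ``min_size`` get label 0.
    """
    n = tom.shape[0]
    if tom.shape != (n, n) or n != len(expr):
        raise ValueError("TOM must be square and match the expression matrix")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    condensed = squareform((diss + diss.T) / 2.0, checks=False)
    tree = linkage(condensed, method="average")
    max_height = tree[:, 2].max()
    raw = fcluster(tree, t=cut_height_frac * max_height, criterion="distance")

    labels = pd.Series(raw, index=expr.index)
    sizes = labels.value_counts()
    small = sizes[sizes < min_size].index
    labels[labels.isin(small)] = UNASSIGNED
    # relabel 1..K by decreasing size
    kept = [m for m in labels.value_counts().index if m != UNASSIGNED]
    remap = {old: new for new, old in enumerate(kept, start=1)}
    remap[UNASSIGNED] = UNASSIGNED
    labels = labels.map(remap)
    if (labels == UNASSIGNED).all():
        warnings.warn("all genes unassigned after size filtering")
        return ModuleSet(labels=labels, eigengenes=pd.DataFrame(), variance_explained={})

    labels = _merge_correlated_modules(expr, labels, merge_cut)
    eigengenes, var_exp = module_eigengenes(expr, labels)
    return ModuleSet(labels=labels, eigengenes=eigengenes, variance_explained=var_exp)


def _merge_correlated_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut: float
) -> pd.Series:
    while True:
        mods = [m for m in sorted(labels.unique()) if m != UNASSIGNED]
        if len(mods) < 2:
            break
        eg, _ = module_eigengenes(expr, labels)
        corr = np.corrcoef(eg.to_numpy())
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                d = 1.0 - corr[i, j]
                if d < merge_cut and (best is None or d < best[0]):
                    best = (d, mods[i], mods[j])
        if best is None:
            break
        _, keep, absorb = best
        labels = labels.replace({absorb: keep})
        logger.info("merged module %d into %d (eigengene dist %.3f)", absorb, keep, best[0])
    # renumber contiguously by size
    kept = [m for m in labels.value_counts().index if m != UNASSIGNED]
    remap = {old: new for new, old in enumerate(kept, start=1)}
    remap[UNASSIGNED] = UNASSIGNED
    return labels.map(remap)


def outlier_cluster_filter(
    eigengenes: pd.DataFrame, threshold: float = 0.5
) -> tuple[list, list, pd.DataFrame]:
    """Flag modules whose eigengene variance is carried by one sample.

    For each module, the statistic is the maximum over samples of
    1 - var(eigengene without that sample) / var(eigengene); modules
    exceeding ``threshold`` are discarded.  Returns (kept labels,
    discarded labels, diagnostics frame).
    """
    if eigengenes.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    kept, discarded, rows = [], [], []
    for m, row in eigengenes.iterrows():
        v = row.to_numpy(dtype=float)
        total = v.var(ddof=1)
        if total == 0:
            discarded.append(m)
            rows.append({"module": m, "max_loo_reduction": np.nan,
                         "driver_sample": None, "discarded": True,
                         "zero_variance": True})
            continue
        n = len(v)
        loo_vars = np.array([np.delete(v, i).var(ddof=1) for i in range(n)])
        reductions = 1.0 - loo_vars / total
        i_max = int(np.argmax(reductions))
        stat = float(reductions[i_max])
        is_out = stat > threshold
        (discarded if is_out else kept).append(m)
        rows.append({"module": m, "max_loo_reduction": stat,
                     "driver_sample": eigengenes.columns[i_max],
                     "discarded": is_out, "zero_variance": False})
    return kept, discarded, pd.DataFrame(rows)


def coexpression_pipeline(
    counts: pd.DataFrame,
    power: int = 4,
    min_size: int = 30,
    merge_cut: float = 0.3,
    cut_height_frac: float = 0.75,
    outlier_threshold: float = 0.5,
    min_mean: float = 1.0,
) -> dict:
    """Counts -> filtered -> normalized -> modules + eigengenes + filter."""
    counts = counts.sort_index().sort_index(axis=1)  # gene/sample-order invariance
    filtered = filter_low_coverage(counts, min_mean=min_mean)
    factors, normalized = median_ratio_normalize(filtered)
    expr = _drop_constant_genes(log_expression(normalized))
    adj = adjacency_matrix(expr, power)
    tom = topological_overlap(adj)
    modules = cluster_modules(
        expr, tom, min_size=min_size,
        cut_height_frac=cut_height_frac, merge_cut=merge_cut,
    )
    if len(modules.eigengenes):
        kept, dropped, diag = outlier_cluster_filter(
            modules.eigengenes, threshold=outlier_threshold
        )
    else:
        kept, dropped, diag = [], [], pd.DataFrame()
    return {
        "size_factors": factors,
        "expression": expr,
        "modules": modules,
        "kept_modules": kept,
        "discarded_modules": dropped,
        "outlier_diagnostics": diag,
        "n_genes_filtered": len(filtered),
    }
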