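"""Module-fitness associations, symbiont AIC comparison, and
cross-experiment stability of module expression."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coralsieve.coexpression import median_ratio_normalize, log_expression

logger = logging.getLogger(__name__)

PHENOTYPES = (
    ("survival", "HV"),
    ("survival", "MV"),
    ("growth", "HV"),
    ("growth", "MV"),
)
SUBSETS = ("all", "MV", "HV")


def _phenotype_vector(scores: pd.DataFrame, trait: str, location: str) -> pd.Series:
    sub = scores[scores["location"] == location]
    return sub.set_index("colony_id")[f"{trait}_score"].dropna()


def _simple_regression(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted q-values (monotone in p)."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def cluster_fitness_regression(
    eigengenes: pd.DataFrame,
    scores: pd.DataFrame,
    subsets: tuple = SUBSETS,
    min_n: int = 3,
) -> pd.DataFrame:
    """Regress each phenotype score on each module eigengene.

    Runs over the full sample and per-origin subsets; raw p comes from
    the slope t-test.  BH q-values are computed across the full-sample
    family (modules x phenotypes) and reported alongside raw p.
    """
    origin_of = scores.drop_duplicates("colony_id").set_index("colony_id")["origin"]
    rows = []
    for module, eg in eigengenes.iterrows():
        for trait, location in PHENOTYPES:
            pheno = _phenotype_vector(scores, trait, location)
            shared = pheno.index.intersection(eg.index)
            for subset in subsets:
                ids = shared if subset == "all" else [
                    c for c in shared if origin_of.get(c) == subset
                ]
                if len(ids) < min_n:
                    logger.info(
                        "skipping module %s %s_%s subset %s: %d colonies",
                        module, trait, location, subset, len(ids),
                    )
                    continue
                x = eg.loc[ids].to_numpy(dtype=float)
                y = pheno.loc[ids].to_numpy(dtype=float)
                if np.std(x) == 0:
                    continue
                slope, r2, p = _simple_regression(y, x)
                rows.append(
                    {
                        "module": module,
                        "phenotype": f"{trait}_{location}",
                        "subset": subset,
                        "n": len(ids),
                        "slope": slope,
                        "r_squared": r2,
                        "p_value": p,
                    }
                )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q_value"] = np.nan
    full = table["subset"] == "all"
    if full.any():
        table.loc[full, "q_value"] = benjamini_hochberg(
            table.loc[full, "p_value"].to_numpy()
        )
    return table


def origin_effect_test(eigengene: pd.Series, origins: pd.Series) -> tuple[float, float]:
    """Welch two-sample t-test of an eigengene by pool of origin."""
    shared = eigengene.index.intersection(origins.index)
    groups = [
        eigengene.loc[[c for c in shared if origins[c] == pool]].to_numpy()
        for pool in ("HV", "MV")
    ]
    if min(len(g) for g in groups) < 2:
        raise ValueError("each origin needs >= 2 colonies")
    t_stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    return float(t_stat), float(p)


def _ols_aic(y: np.ndarray, x: np.ndarray) -> float:
    """AIC of a simple linear regression under the Gaussian ML likelihood
    (k = intercept + slope + residual variance = 3)."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return -2.0 * loglik + 2.0 * 3


def aic_symbiont_comparison(
    score: pd.Series, eigengene: pd.Series, clade_d: pd.Series
) -> dict:
    """Compare eigengene vs symbiont clade-D proportion as predictors of
    a fitness score by AIC of the two least-squares fits."""
    shared = score.index.intersection(eigengene.index).intersection(clade_d.index)
    frame = pd.DataFrame(
        {"score": score.loc[shared], "eigengene": eigengene.loc[shared],
         "clade_d": clade_d.loc[shared]}
    )
    n_dropped = int(frame.isna().any(axis=1).sum())
    frame = frame.dropna()
    y = frame["score"].to_numpy(dtype=float)
    aic_expr = _ols_aic(y, frame["eigengene"].to_numpy(dtype=float))
    aic_symb = _ols_aic(y, frame["clade_d"].to_numpy(dtype=float))
    return {
        "aic_expression": aic_expr,
        "aic_symbiont": aic_symb,
        "delta_aic": aic_expr - aic_symb,
        "n": len(frame),
        "n_dropped_missing": n_dropped,
    }


@dataclass
class StabilityRecord:
    module: int
    panel: str
    correlation: float
    p_value: float
    n_shared_samples: int
    n_genes_used: int


def stability_projection(
    module_genes: list,
    original_eigengene: pd.Series,
    panels: dict,
    min_gene_frac: float = 0.5,
) -> pd.DataFrame:
    """Project a module onto follow-up count panels and correlate PC1s.

    Each panel is median-ratio normalized, restricted to the module's
    genes, standardized, reduced to its first principal component over
    the shared samples, sign-oriented to the original eigengene, and
    correlated with it (Pearson r + p).
    """
    rows = []
    for panel_id, counts in panels.items():
        present = [g for g in module_genes if g in counts.index]
        if len(present) < min_gene_frac * len(module_genes):
            raise ValueError(
                f"panel {panel_id}: only {len(present)}/{len(module_genes)} "
                "module genes present"
            )
        shared = original_eigengene.index.intersection(counts.columns)
        if len(shared) < 3:
            raise ValueError(f"panel {panel_id}: fewer than 3 shared samples")
        _, normalized = median_ratio_normalize(counts)
        expr = log_expression(normalized.loc[present, shared])
        z = expr.to_numpy(dtype=float)
        mu = z.mean(axis=1, keepdims=True)
        sd = z.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0
        z = (z - mu) / sd
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        pc1 = vt[0]
        ref = original_eigengene.loc[shared].to_numpy(dtype=float)
        if np.dot(pc1, ref) < 0:
            pc1 = -pc1
        res = stats.pearsonr(pc1, ref)
        rows.append(
            StabilityRecord(
                module=-1,
                panel=str(panel_id),
                correlation=float(res.statistic),
                p_value=float(res.pvalue),
                n_shared_samples=len(shared),
                n_genes_used=len(present),
            ).__dict__
        )
    return pd.DataFrame(rows)
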