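"""Colony-level fitness inference for the reciprocal transplant.

Covers proportional-survival summaries, crate-normalized colony scores,
binomial/Gaussian mixed models with crossed random intercepts (colony
and crate) fit by maximum likelihood, backward-AIC model selection,
reaction norms, the survival-variance permutation test, its sensitivity
perturbations, and the survival-growth trade-off regression.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_solve
from scipy.special import expit
from scipy.stats import t as t_dist

logger = logging.getLogger(__name__)

FULL_FIXED = ("origin", "location", "origin:location")
FULL_RANDOM = ("colony_id", "crate_id")


# ---------------------------------------------------------------------------
# proportional survival and crate-normalized scores
# ---------------------------------------------------------------------------

def tracked(fragments: pd.DataFrame) -> pd.DataFrame:
    """Fragments whose fate is known (alive or dead)."""
    return fragments[fragments["fate"].isin(("alive", "dead"))]


def colony_proportional_survival(
    fragments: pd.DataFrame, by_location: bool = False
) -> pd.Series:
    """Per-colony fraction of tracked fragments that survived.

    Missing fragments are excluded from the denominator.  Colonies whose
    fragments are all missing get NaN.  With ``by_location`` the index
    is (colony_id, location).
    """
    frame = fragments.copy()
    frame["alive"] = (frame["fate"] == "alive").astype(float)
    frame["is_tracked"] = frame["fate"].isin(("alive", "dead"))
    keys = ["colony_id", "location"] if by_location else ["colony_id"]
    grouped = frame.groupby(keys)
    n_tracked = grouped["is_tracked"].sum()
    n_alive = grouped.apply(
        lambda g: g.loc[g["is_tracked"], "alive"].sum(), include_groups=False
    )
    prop = n_alive / n_tracked
    prop.name = "proportional_survival"
    untracked = prop.index[n_tracked == 0]
    if len(untracked):
        logger.warning("colonies with no tracked fragments: %s", list(untracked))
    return prop


def crate_normalized_scores(fragments: pd.DataFrame) -> pd.DataFrame:
    """Per-colony, per-location crate-normalized survival and growth scores.

    Within each destination pool, fragment values are regressed on crate
    indicators by OLS (equivalently: crate means are subtracted) and the
    residuals are averaged per colony.  Survival residuals use the 0/1
    outcome over tracked fragments; growth residuals use survivors only.
    """
    rows = []
    for location, pool_df in tracked(fragments).groupby("location"):
        surv = pool_df.assign(value=(pool_df["fate"] == "alive").astype(float))
        surv_res = _crate_residuals(surv)
        grow = pool_df[pool_df["fate"] == "alive"].assign(
            value=pool_df.loc[pool_df["fate"] == "alive", "growth"]
        )
        grow_res = _crate_residuals(grow)
        for colony, cdf in surv.groupby("colony_id"):
            g_idx = grow_res.index.intersection(cdf.index)
            rows.append(
                {
                    "colony_id": colony,
                    "origin": cdf["origin"].iloc[0],
                    "location": location,
                    "survival_score": float(surv_res.loc[cdf.index].mean()),
                    "growth_score": (
                        float(grow_res.loc[g_idx].mean()) if len(g_idx) else np.nan
                    ),
                    "n_fragments_survival": int(len(cdf)),
                    "n_fragments_growth": int(len(g_idx)),
                }
            )
    return pd.DataFrame(rows)


def _crate_residuals(df: pd.DataFrame) -> pd.Series:
    """OLS residuals of ``value`` on crate indicators = value - crate mean."""
    if df.empty:
        return pd.Series(dtype=float)
    counts = df.groupby("crate_id")["value"].count()
    empty = counts[counts == 0]
    if len(empty):
        logger.warning("crates with no tracked fragments skipped: %s", list(empty.index))
    crate_means = df.groupby("crate_id")["value"].transform("mean")
    return df["value"] - crate_means


# ---------------------------------------------------------------------------
# mixed models (ML, Laplace approximation for binomial)
# ---------------------------------------------------------------------------

@dataclass
class MixedModelFit:
    family: str
    fixed_terms: tuple
    random_terms: tuple
    coef: dict  # term name -> estimate
    coef_se: dict
    coef_cov: np.ndarray
    random_sd: dict  # factor -> SD of random intercepts
    resid_sd: float | None  # gaussian only
    loglik: float
    n_obs: int
    converged: bool
    separation_warning: bool = False

    @property
    def n_params(self) -> int:
        k = len(self.coef) + len(self.random_sd)
        if self.family == "gaussian":
            k += 1
        return k

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params


def _design_matrix(df: pd.DataFrame, fixed_terms) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design: intercept + MV-origin + MV-location (+ product)."""
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    o = (df["origin"].to_numpy() == "MV").astype(float)
    l = (df["location"].to_numpy() == "MV").astype(float)
    if "origin" in fixed_terms:
        cols.append(o)
        names.append("originMV")
    if "location" in fixed_terms:
        cols.append(l)
        names.append("locationMV")
    if "origin:location" in fixed_terms:
        if "origin" not in fixed_terms or "location" not in fixed_terms:
            raise ValueError("interaction requires both main effects")
        cols.append(o * l)
        names.append("originMV:locationMV")
    return np.column_stack(cols), names


def _random_design(df: pd.DataFrame, random_terms) -> list[np.ndarray]:
    mats = []
    for term in random_terms:
        codes, _ = pd.factorize(df[term], sort=True)
        z = np.zeros((len(df), codes.max() + 1))
        z[np.arange(len(df)), codes] = 1.0
        mats.append(z)
    return mats


def _binomial_laplace_loglik(
    params: np.ndarray, y, X, Zs, q_sizes
) -> float:
    """Negative Laplace-approximate marginal log-likelihood.

    params = (beta, log_sd per random factor).  The random-effect mode
    is found by Newton iterations on the penalized joint likelihood.
    """
    p = X.shape[1]
    beta = params[:p]
    sds = np.exp(params[p:])
    q_total = sum(q_sizes)
    if q_total == 0:
        eta = X @ beta
        return -_bernoulli_ll(y, eta)

    Z = np.hstack(Zs)
    d_inv = np.concatenate(
        [np.full(q, 1.0 / max(sd, 1e-8) ** 2) for q, sd in zip(q_sizes, sds)]
    )
    u = np.zeros(q_total)
    offset = X @ beta
    for _ in range(50):
        eta = offset + Z @ u
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        grad = Z.T @ (y - mu) - d_inv * u
        H = Z.T @ (Z * w[:, None])
        H[np.diag_indices_from(H)] += d_inv
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return np.inf
        u_new = u + step
        if np.max(np.abs(step)) < 1e-9:
            u = u_new
            break
        u = u_new
    eta = offset + Z @ u
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = Z.T @ (Z * w[:, None])
    H[np.diag_indices_from(H)] += d_inv
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return np.inf
    joint = (
        _bernoulli_ll(y, eta)
        - 0.5 * np.sum(d_inv * u**2)
        + 0.5 * np.sum(np.log(d_inv))
        - 0.5 * q_total * np.log(2.0 * np.pi)
    )
    marginal = joint + 0.5 * q_total * np.log(2.0 * np.pi) - 0.5 * logdet_H
    return -marginal


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # log(1 + e^eta) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _gaussian_profile_loglik(log_sds: np.ndarray, y, X, Zs) -> tuple[float, np.ndarray, np.ndarray]:
    """Exact ML log-likelihood with beta profiled out by GLS.

    log_sds = (log sd per random factor..., log resid sd).  Returns
    (loglik, beta_hat, cov_beta).
    """
    n = len(y)
    sds = np.exp(log_sds)
    resid_var = sds[-1] ** 2
    V = np.eye(n) * resid_var
    for z, sd in zip(Zs, sds[:-1]):
        V += sd**2 * (z @ z.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.zeros(X.shape[1]), np.eye(X.shape[1])
    Vinv_X = cho_solve((L, True), X)
    Vinv_y = cho_solve((L, True), y)
    XtVinvX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    r = y - X @ beta
    Vinv_r = cho_solve((L, True), r)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2.0 * np.pi) + logdet + r @ Vinv_r)
    cov_beta = np.linalg.inv(XtVinvX)
    return float(ll), beta, cov_beta


def fit_glmm(
    fragments: pd.DataFrame,
    fixed: tuple = FULL_FIXED,
    random: tuple = FULL_RANDOM,
    family: str = "binomial",
    outcome: str | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> MixedModelFit:
    """ML fit of a GLMM with crossed random intercepts.

    Binomial fits use a Laplace approximation of the marginal
    likelihood; Gaussian fits use the exact marginal (still ML, not
    REML, so AICs are comparable across fixed-effect structures).
    Growth models use survivors only; survival models use all tracked
    fragments.
    """
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    df = tracked(fragments)
    if family == "binomial":
        outcome = outcome or "alive"
        df = df.assign(alive=(df["fate"] == "alive").astype(float))
    else:
        outcome = outcome or "growth"
        df = df[df[outcome].notna()]
    y = df[outcome].to_numpy(dtype=float)
    X, names = _design_matrix(df, fixed)
    Zs = _random_design(df, random)
    q_sizes = [z.shape[1] for z in Zs]
    rng = np.random.default_rng(seed)

    if family == "gaussian":
        return _fit_gaussian(y, X, names, Zs, q_sizes, fixed, random, rng, n_restarts)
    return _fit_binomial(y, X, names, Zs, q_sizes, fixed, random, rng, n_restarts)


def _fit_gaussian(y, X, names, Zs, q_sizes, fixed, random, rng, n_restarts):
    n_var = len(Zs) + 1
    resid0 = np.log(np.std(y) + 1e-8)
    best = None
    starts = [np.concatenate([np.full(len(Zs), resid0 - 1.0), [resid0]])]
    for _ in range(n_restarts - 1):
        starts.append(starts[0] + rng.normal(0, 1.0, size=n_var))
    for x0 in starts:
        res = optimize.minimize(
            lambda p: -_gaussian_profile_loglik(p, y, X, Zs)[0],
            x0,
            method="L-BFGS-B",
            bounds=[(-10.0, 6.0)] * n_var,
        )
        if best is None or res.fun < best.fun:
            best = res
    ll, beta, cov_beta = _gaussian_profile_loglik(best.x, y, X, Zs)
    sds = np.exp(best.x)
    return MixedModelFit(
        family="gaussian",
        fixed_terms=tuple(fixed),
        random_terms=tuple(random),
        coef=dict(zip(names, beta)),
        coef_se=dict(zip(names, np.sqrt(np.diag(cov_beta)))),
        coef_cov=cov_beta,
        random_sd={t: float(s) for t, s in zip(random, sds[:-1])},
        resid_sd=float(sds[-1]),
        loglik=float(ll),
        n_obs=len(y),
        converged=bool(best.success),
    )


def _fit_binomial(y, X, names, Zs, q_sizes, fixed, random, rng, n_restarts):
    p = X.shape[1]
    separation = False
    # GLM start via a few IRLS steps
    beta0 = np.zeros(p)
    for _ in range(25):
        eta = X @ beta0
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        try:
            beta_new = beta0 + np.linalg.solve(
                X.T @ (X * w[:, None]), X.T @ (y - mu)
            )
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta0)) < 1e-10:
            beta0 = beta_new
            break
        beta0 = beta_new
    if np.max(np.abs(beta0)) > 15:
        separation = True
        warnings.warn("possible complete separation in binomial fit")

    def objective(params):
        return _binomial_laplace_loglik(params, y, X, Zs, q_sizes)

    n_var = len(Zs)
    best = None
    starts = [np.concatenate([beta0, np.full(n_var, np.log(0.5 + 1e-8))])]
    for _ in range(n_restarts - 1):
        jitter = np.concatenate(
            [rng.normal(0, 0.5, size=p), rng.normal(0, 1.0, size=n_var)]
        )
        starts.append(starts[0] + jitter)
    bounds = [(None, None)] * p + [(-10.0, 3.0)] * n_var
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ll = -best.fun
    beta = best.x[:p]
    sds = np.exp(best.x[p:]) if n_var else np.array([])

    cov_beta = _wald_cov(objective, best.x, p)
    return MixedModelFit(
        family="binomial",
        fixed_terms=tuple(fixed),
        random_terms=tuple(random),
        coef=dict(zip(names, beta)),
        coef_se=dict(zip(names, np.sqrt(np.diag(cov_beta)))),
        coef_cov=cov_beta,
        random_sd={t: float(s) for t, s in zip(random, sds)},
        resid_sd=None,
        loglik=float(ll),
        n_obs=len(y),
        converged=bool(best.success),
        separation_warning=separation,
    )


def _wald_cov(objective, x_opt: np.ndarray, p: int) -> np.ndarray:
    """Fixed-effect covariance from a finite-difference Hessian of the
    negative marginal log-likelihood (beta block only)."""
    h = 1e-4
    k = len(x_opt)
    H = np.zeros((k, k))
    f0 = objective(x_opt)
    for i in range(k):
        for j in range(i, k):
            xi = x_opt.copy(); xi[i] += h
            xj = x_opt.copy(); xj[j] += h
            xij = x_opt.copy(); xij[i] += h; xij[j] += h
            H[i, j] = H[j, i] = (objective(xij) - objective(xi) - objective(xj) + f0) / h**2
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return cov[:p, :p]


# ---------------------------------------------------------------------------
# model selection, reaction norms
# ---------------------------------------------------------------------------

def _droppable(terms: tuple) -> list[str]:
    """Terms removable while respecting marginality (interaction first)."""
    terms = list(terms)
    if "origin:location" in terms:
        return ["origin:location"]
    return [t for t in terms]


def stepwise_select(
    fragments: pd.DataFrame,
    family: str = "binomial",
    outcome: str | None = None,
    random: tuple = FULL_RANDOM,
    n_restarts: int = 1,
    seed: int = 0,
) -> tuple[MixedModelFit, list]:
    """Backward AIC elimination from the full fixed structure.

    At each step the term whose removal lowers AIC most is dropped;
    stops when no removal lowers AIC.  Returns the selected fit and the
    trail of (fixed terms, AIC) considered along the accepted path.
    """
    terms = tuple(FULL_FIXED)
    fit = fit_glmm(fragments, terms, random, family, outcome, n_restarts, seed)
    trail = [(terms, fit.aic)]
    while True:
        candidates = []
        for term in _droppable(terms):
            reduced = tuple(t for t in terms if t != term)
            cand = fit_glmm(fragments, reduced, random, family, outcome, n_restarts, seed)
            candidates.append((cand.aic, reduced, cand))
        candidates.sort(key=lambda c: c[0])
        if not candidates or candidates[0][0] >= fit.aic:
            break
        _, terms, fit = candidates[0]
        trail.append((terms, fit.aic))
        logger.info("stepwise: kept %s (AIC %.2f)", terms, fit.aic)
        if not terms:
            break
    return fit, trail


def reaction_norms(fit: MixedModelFit) -> pd.DataFrame:
    """Cell means and Wald 95% CIs per origin x location from a full fit.

    CIs are computed on the link scale and back-transformed, so binomial
    endpoints always lie in (0, 1).
    """
    if not fit.converged:
        raise RuntimeError("reaction norms require a converged fit")
    names = list(fit.coef)
    beta = np.array([fit.coef[n] for n in names])
    rows = []
    for origin, location in itertools.product(("HV", "MV"), ("HV", "MV")):
        contrast = np.zeros(len(names))
        for i, n in enumerate(names):
            if n == "(Intercept)":
                contrast[i] = 1.0
            elif n == "originMV":
                contrast[i] = float(origin == "MV")
            elif n == "locationMV":
                contrast[i] = float(location == "MV")
            elif n == "originMV:locationMV":
                contrast[i] = float(origin == "MV" and location == "MV")
        eta = float(contrast @ beta)
        var = float(contrast @ fit.coef_cov @ contrast)
        if not np.isfinite(var) or var < 0:
            raise RuntimeError("CI undefined (boundary or singular fit)")
        half = 1.959963984540054 * np.sqrt(var)
        lo, hi = eta - half, eta + half
        if fit.family == "binomial":
            mean, lo, hi = expit(eta), expit(lo), expit(hi)
        else:
            mean = eta
        rows.append(
            {"origin": origin, "location": location, "mean": mean,
             "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation variance test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    observed_sd: float
    null_sds: np.ndarray
    p_one_sided: float
    n_perm: int
    seed: int
    origin_group: str
    degenerate: bool = False


def survival_sd_permutation_test(
    fragments: pd.DataFrame,
    origin_group: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """One-sided permutation test for heterogeneity in colony survival.

    Observed statistic: SD over colonies (of the given origin) of
    proportional survival, pooled over both destination pools.  Null
    draws shuffle tracked-fragment outcomes among the group's fragments
    within each destination pool (preserving per-pool death totals);
    p = #{null >= observed} / n_perm.
    """
    df = tracked(fragments)
    df = df[df["origin"] == origin_group]
    # canonical order so p is invariant to input row order under a fixed seed
    df = df.sort_values("fragment_id", kind="mergesort")
    if df["colony_id"].nunique() < 2:
        raise ValueError("need >= 2 colonies in the origin group")
    colonies = sorted(df["colony_id"].unique())
    col_idx = {c: i for i, c in enumerate(colonies)}
    alive = (df["fate"] == "alive").to_numpy(dtype=float)
    colony_codes = df["colony_id"].map(col_idx).to_numpy()
    tracked_per_colony = np.bincount(colony_codes, minlength=len(colonies)).astype(float)

    observed_prop = (
        np.bincount(colony_codes, weights=alive, minlength=len(colonies))
        / tracked_per_colony
    )
    observed_sd = float(np.std(observed_prop, ddof=1))

    rng = np.random.default_rng(seed)
    alive_counts = np.zeros((n_perm, len(colonies)))
    for _, pool_df in df.groupby("location"):
        mask = df.index.isin(pool_df.index)
        pool_alive = alive[mask]
        pool_codes = colony_codes[mask]
        n = len(pool_alive)
        onehot = np.zeros((n, len(colonies)))
        onehot[np.arange(n), pool_codes] = 1.0
        # batch permutations: argsort of uniform keys = uniform random permutation
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        permuted = pool_alive[order]  # (n_perm, n)
        alive_counts += permuted @ onehot

    null_props = alive_counts / tracked_per_colony
    null_sds = np.std(null_props, axis=1, ddof=1)
    p = float(np.mean(null_sds >= observed_sd))

    degenerate = False
    if alive.sum() == len(alive) or alive.sum() == 0:
        degenerate = True
        warnings.warn(
            f"degenerate null for origin {origin_group}: no variation in outcomes"
        )
    return PermutationResult(
        observed_sd=observed_sd,
        null_sds=null_sds,
        p_one_sided=p,
        n_perm=n_perm,
        seed=seed,
        origin_group=origin_group,
        degenerate=degenerate,
    )


def sensitivity_permutations(
    fragments: pd.DataFrame,
    mode: str,
    origin_group: str = "MV",
    reference_group: str = "HV",
    k: int = 2,
    n_outer: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of perturbed replicates where the SD test stays significant.

    ``match_n`` subsamples the tested group's colonies down to the
    reference group's colony count each replicate; ``drop_worst_k``
    removes the k lowest-survival colonies (deterministic perturbation,
    fresh permutations per replicate).
    """
    if mode not in ("match_n", "drop_worst_k"):
        raise ValueError(f"unknown mode {mode!r}")
    df = tracked(fragments)
    group = df[df["origin"] == origin_group]
    colonies = sorted(group["colony_id"].unique())
    rng = np.random.default_rng(seed)

    if mode == "drop_worst_k":
        if k >= len(colonies):
            raise ValueError("k must be smaller than the group size")
        props = colony_proportional_survival(group)
        worst = props.sort_values().index[:k]
        kept = [c for c in colonies if c not in set(worst)]
    else:
        n_target = df[df["origin"] == reference_group]["colony_id"].nunique()
        if n_target > len(colonies):
            raise ValueError("reference group larger than tested group")

    n_sig = 0
    for _ in range(n_outer):
        if mode == "match_n":
            kept_rep = list(rng.choice(colonies, size=n_target, replace=False))
        else:
            kept_rep = kept
        sub = fragments[
            (fragments["origin"] != origin_group)
            | fragments["colony_id"].isin(kept_rep)
        ]
        res = survival_sd_permutation_test(
            sub, origin_group, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        n_sig += res.p_one_sided < alpha
    return n_sig / n_outer


# ---------------------------------------------------------------------------
# trade-off regression
# ---------------------------------------------------------------------------

@dataclass
class TradeoffResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    leverage_trail: pd.DataFrame = field(repr=False, default=None)


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least squares returning (beta, R^2, p-value of the first slope)."""
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    dof = n - p
    if dof <= 0:
        return beta, r2, np.nan
    sigma2 = ss_res / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    t_stat = beta[1] / se if se > 0 else np.inf
    p_val = 2.0 * t_dist.sf(abs(t_stat), dof)
    return beta, r2, float(p_val)


def tradeoff_regression(
    scores: pd.DataFrame,
    x: tuple = ("survival", "HV"),
    y: tuple = ("growth", "MV"),
    include_origin: bool = True,
) -> TradeoffResult:
    """OLS of one colony score on another, with origin as an additive
    indicator, plus leave-one-colony-out refits for influence analysis.

    ``x`` / ``y`` are (trait, location) pairs, e.g. survival score in
    the HV pool against growth score in the MV pool.
    """
    def pick(trait, location):
        col = f"{trait}_score"
        sub = scores[scores["location"] == location][["colony_id", "origin", col]]
        return sub.rename(columns={col: trait}).dropna()

    merged = pick(*x).merge(pick(*y), on=["colony_id", "origin"])
    xs = merged[x[0]].to_numpy(dtype=float)
    ys = merged[y[0]].to_numpy(dtype=float)
    if len(merged) < 3:
        raise ValueError("need >= 3 colonies with both scores")
    if np.std(xs) == 0:
        raise ValueError("zero variance in the predictor score")

    def design(sub):
        cols = [np.ones(len(sub)), sub[x[0]].to_numpy(dtype=float)]
        if include_origin and sub["origin"].nunique() > 1:
            cols.append((sub["origin"] == "MV").to_numpy(dtype=float))
        return np.column_stack(cols)

    beta, r2, p = _ols(ys, design(merged))

    trail = []
    for cid in merged["colony_id"]:
        sub = merged[merged["colony_id"] != cid]
        if len(sub) < 3 or np.std(sub[x[0]]) == 0:
            continue
        b_i, r2_i, p_i = _ols(sub[y[0]].to_numpy(dtype=float), design(sub))
        trail.append(
            {"left_out": cid, "slope": b_i[1], "r_squared": r2_i, "p_value": p_i}
        )
    return TradeoffResult(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r_squared=float(r2),
        p_value=float(p),
        n=len(merged),
        leverage_trail=pd.DataFrame(trail),
    )
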