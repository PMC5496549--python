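"""Independent reference implementations used to check the package.

Everything here is deliberately naive (loops, quadrature, closed forms)
and shares no code with the implementation paths it validates.
"""

import numpy as np
from numpy.polynomial.hermite_e import hermegauss


def gh_marginal_loglik_binomial(
    beta: np.ndarray,
    sd: float,
    y: np.ndarray,
    X: np.ndarray,
    group_codes: np.ndarray,
    n_nodes: int = 61,
) -> float:
    """Gauss-Hermite marginal log-likelihood for a binomial model with a
    single random intercept (probabilists' quadrature)."""
    nodes, weights = hermegauss(n_nodes)
    weights = weights / np.sqrt(2.0 * np.pi)
    eta0 = X @ beta
    total = 0.0
    for g in np.unique(group_codes):
        m = group_codes == g
        etas = eta0[m][:, None] + sd * nodes[None, :]
        lls = (y[m][:, None] * etas - np.logaddexp(0.0, etas)).sum(axis=0)
        mx = lls.max()
        total += mx + np.log(np.sum(weights * np.exp(lls - mx)))
    return float(total)


def tom_brute_force(adjacency: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        k_i = sum(a[i, u] for u in range(n) if u != i)
        for j in range(n):
            if i == j:
                continue
            k_j = sum(a[j, u] for u in range(n) if u != j)
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k_i, k_j) + 1.0 - a[i, j])
    return tom


def two_gene_variance_explained(r: float) -> float:
    """PC1 variance fraction for two standardized genes with correlation
    r: eigenvalues of [[1, r], [r, 1]] are 1 +/- |r|."""
    return (1.0 + abs(r)) / 2.0


def bh_naive(pvals):
    """Textbook step-up Benjamini-Hochberg."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = val
        prev = val
    return q


def sd_of_colony_proportions(fragments) -> float:
    """Loop-based SD (ddof=1) of per-colony tracked survival proportions."""
    props = []
    for colony in sorted(fragments["colony_id"].unique()):
        sub = fragments[fragments["colony_id"] == colony]
        sub = sub[sub["fate"].isin(("alive", "dead"))]
        if len(sub):
            props.append((sub["fate"] == "alive").mean())
    return float(np.std(props, ddof=1))
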