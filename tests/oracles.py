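"""Independent reference implementations used to cross-check the package.

Everything here deliberately takes the slow, textbook route: dense V-matrix
likelihoods, derivative-free maximization, gene-dropping Monte Carlo, and the
balanced one-way ANOVA estimator. None of it shares code with the package's
sparse mixed-model-equation path.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from codsge.reml import VarianceComponents


def dense_reml_loglik(theta: VarianceComponents, mm, A: np.ndarray) -> float:
    """REML log-likelihood via the textbook dense formula
    −½[(N−p)log 2π + log|V| + log|XᵀV⁻¹X| + yᵀPy]."""
    y, X = mm.y, mm.X
    n = len(y)
    ZD = mm.Z_D.toarray()
    V = theta.sigma2_AD * ZD @ A @ ZD.T + theta.sigma2_e * np.eye(n)
    if mm.Z_S is not None:
        ZS = mm.Z_S.toarray()
        V += theta.sigma2_AS * ZS @ A @ ZS.T
        V += theta.sigma_ADS * (ZD @ A @ ZS.T + ZS @ A @ ZD.T)
    if mm.W_c is not None:
        Wc = mm.W_c.toarray()
        V += theta.sigma2_c * Wc @ Wc.T
    if mm.W_t is not None:
        Wt = mm.W_t.toarray()
        V += theta.sigma2_t * Wt @ Wt.T
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtViX)
    p = X.shape[1]
    return float(-0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldX + y @ P @ y))


def brute_force_reml_optimum(mm, A: np.ndarray, social: bool, s: float) -> float:
    """Best restricted log-likelihood found by derivative-free search over the
    dense likelihood, from several starts. Parameters are transformed (log
    variances, Cholesky of G) exactly as a constrained search requires, but
    the objective is the dense formula above."""

    def theta_of(x):
        if social:
            l11 = np.sqrt(s) * np.exp(x[0])
            l21 = np.sqrt(s) * x[1]
            l22 = np.sqrt(s) * np.exp(x[2])
            return VarianceComponents(
                sigma2_AD=l11**2,
                sigma_ADS=l11 * l21,
                sigma2_AS=l21**2 + l22**2,
                sigma2_c=s * np.exp(x[3]),
                sigma2_t=s * np.exp(x[4]),
                sigma2_e=s * np.exp(x[5]),
            )
        return VarianceComponents(
            sigma2_AD=s * np.exp(x[0]),
            sigma2_c=s * np.exp(x[1]),
            sigma2_t=s * np.exp(x[2]),
            sigma2_e=s * np.exp(x[3]),
        )

    def obj(x):
        try:
            return -dense_reml_loglik(theta_of(x), mm, A)
        except np.linalg.LinAlgError:
            return np.inf

    if social:
        starts = [
            np.array([-0.8, 0.0, -2.0, np.log(0.2), np.log(0.2), np.log(0.2)]),
            np.array([-1.5, 0.1, -3.0, np.log(0.1), np.log(0.1), np.log(0.5)]),
            np.array([-0.3, -0.1, -4.0, np.log(0.05), np.log(0.3), np.log(0.3)]),
        ]
    else:
        starts = [
            np.full(4, np.log(0.25)),
            np.array([np.log(0.5), np.log(0.05), np.log(0.05), np.log(0.4)]),
            np.array([np.log(0.05), np.log(0.3), np.log(0.3), np.log(0.35)]),
        ]
    best = np.inf
    for x0 in starts:
        r = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            options={"maxiter": 6000, "maxfev": 6000, "fatol": 1e-10, "xatol": 1e-7},
        )
        best = min(best, r.fun)
    return -best


def gene_dropping_A(ped, n_rep: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo estimate of the relationship matrix by dropping founder
    alleles through the pedigree: A_ij = 2 × P(two alleles drawn at random,
    one from i and one from j, are identical by descent)."""
    n = len(ped)
    alleles = np.zeros((n_rep, n, 2), dtype=np.int64)
    next_allele = 0
    for k in range(n):
        s, d = ped.sire[k], ped.dam[k]
        for slot, parent in enumerate((s, d)):
            if parent < 0:
                alleles[:, k, slot] = next_allele
                next_allele += 1
            else:
                pick = rng.integers(0, 2, size=n_rep)
                alleles[:, k, slot] = alleles[np.arange(n_rep), parent, pick]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            match = (
                (alleles[:, i, 0] == alleles[:, j, 0]).astype(float)
                + (alleles[:, i, 0] == alleles[:, j, 1])
                + (alleles[:, i, 1] == alleles[:, j, 0])
                + (alleles[:, i, 1] == alleles[:, j, 1])
            )
            A[i, j] = 0.5 * match.mean()
    return A


def anova_halfsib_sigma2A(y: np.ndarray, sire_idx: np.ndarray) -> tuple[float, float]:
    """Balanced paternal half-sib ANOVA (expected mean squares) estimator.

    Returns (σ²_A, σ²_within) with σ²_A = 4·σ²_sire; requires equal family
    sizes."""
    sires = np.unique(sire_idx)
    k = len(y) // len(sires)
    means = np.array([y[sire_idx == s_].mean() for s_ in sires])
    grand = y.mean()
    msb = k * np.sum((means - grand) ** 2) / (len(sires) - 1)
    ssw = sum(np.sum((y[sire_idx == s_] - means[i]) ** 2) for i, s_ in enumerate(sires))
    msw = ssw / (len(y) - len(sires))
    sigma2_s = (msb - msw) / k
    return 4.0 * sigma2_s, msw
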