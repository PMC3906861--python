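"""Derived genetic parameters of the direct + social animal model.

For group size n (fish per tank), the total breeding value of an individual
is TBV = a_D + (n−1)·a_S, giving the total heritable variance

    σ²_TBV = σ²_AD + 2(n−1)·σ_ADS + (n−1)²·σ²_AS,

and the phenotypic variance of a group member among unrelated group mates

    σ²_P = σ²_AD + (n−1)·σ²_AS + σ²_c + σ²_t + σ²_e.

Ratios: T² = σ²_TBV/σ²_P (can exceed 1: an individual's heritable impact is
spread over its whole group), h² = σ²_AD/σ²_P, and the direct–social genetic
correlation r_AS,AD = σ_ADS/√(σ²_AD σ²_AS). Standard errors are first-order
delta-method transforms of the REML sampling covariance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reml import COMPONENTS, ModelFit, VarianceComponents

#: nominal fish per experimental tank in the emulated design
DEFAULT_GROUP_SIZE = 21


def total_breeding_variance(vc: VarianceComponents, n: int = DEFAULT_GROUP_SIZE) -> float:
    """σ²_TBV = σ²_AD + 2(n−1)σ_ADS + (n−1)²σ²_AS."""
    if n < 2:
        raise ValueError("group size n must be at least 2")
    m = n - 1
    return vc.sigma2_AD + 2.0 * m * vc.sigma_ADS + m * m * vc.sigma2_AS


def phenotypic_variance(
    vc: VarianceComponents, n: int = DEFAULT_GROUP_SIZE, model: str = "social"
) -> float:
    """σ²_P = σ²_AD + (n−1)σ²_AS + σ²_c + σ²_t + σ²_e (unrelated group mates).

    Under the conventional model the social term is absent.
    """
    if n < 2:
        raise ValueError("group size n must be at least 2")
    social_term = (n - 1) * vc.sigma2_AS if model == "social" else 0.0
    return vc.sigma2_AD + social_term + vc.sigma2_c + vc.sigma2_t + vc.sigma2_e


def heritability(vc: VarianceComponents, n: int = DEFAULT_GROUP_SIZE, model: str = "social") -> float:
    return vc.sigma2_AD / phenotypic_variance(vc, n, model)


def t_squared(vc: VarianceComponents, n: int = DEFAULT_GROUP_SIZE) -> float:
    return total_breeding_variance(vc, n) / phenotypic_variance(vc, n, "social")


def direct_social_correlation(vc: VarianceComponents) -> float:
    """r_AS,AD = σ_ADS / √(σ²_AD σ²_AS); NaN when either variance is zero."""
    denom = vc.sigma2_AD * vc.sigma2_AS
    if denom <= 0:
        return float("nan")
    return vc.sigma_ADS / np.sqrt(denom)


def partition(vc: VarianceComponents, n: int = DEFAULT_GROUP_SIZE) -> tuple[float, float, float]:
    """Percentage shares of σ²_TBV: direct, direct–social covariance, social."""
    tbv = total_breeding_variance(vc, n)
    if tbv <= 0:
        raise ValueError("total breeding variance must be positive to partition")
    m = n - 1
    return (
        100.0 * vc.sigma2_AD / tbv,
        100.0 * 2.0 * m * vc.sigma_ADS / tbv,
        100.0 * m * m * vc.sigma2_AS / tbv,
    )


@dataclass
class DerivedParameters:
    """Derived parameters with delta-method standard errors."""

    n: int
    model: str
    sigma2_TBV: float
    sigma2_P: float
    T2: float
    h2: float
    r_AS_AD: float
    se_sigma2_TBV: float
    se_sigma2_P: float
    se_T2: float
    se_h2: float
    se_r_AS_AD: float
    shares: tuple[float, float, float] | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("sigma2_TBV", self.sigma2_TBV, self.se_sigma2_TBV),
            ("sigma2_P", self.sigma2_P, self.se_sigma2_P),
            ("T2", self.T2, self.se_T2),
            ("h2", self.h2, self.se_h2),
            ("r_AS_AD", self.r_AS_AD, self.se_r_AS_AD),
        ]
        df = pd.DataFrame(rows, columns=["parameter", "estimate", "se"])
        df["model"] = self.model
        df["n"] = self.n
        return df


def _delta_se(func, vc: VarianceComponents, cov: np.ndarray) -> float:
    """First-order delta-method SE of func(vc) under sampling covariance cov."""
    vals = vc.as_array()
    grad = np.zeros(6)
    for k in range(6):
        if np.all(cov[k] == 0) and cov[k, k] == 0:
            continue
        h = 1e-4 * max(abs(vals[k]), 1e-8)
        up, dn = vals.copy(), vals.copy()
        up[k] += h
        dn[k] -= h
        try:
            f_up = func(VarianceComponents.from_array(up))
            f_dn = func(VarianceComponents.from_array(dn))
        except ValueError:
            continue
        grad[k] = (f_up - f_dn) / (2 * h)
    var = float(grad @ cov @ grad)
    return float(np.sqrt(max(var, 0.0)))


def derive(fit: ModelFit, n: int = DEFAULT_GROUP_SIZE) -> DerivedParameters:
    """All derived parameters for a fitted model at group size ``n``.

    ``r_AS_AD`` is NaN when either genetic variance is a boundary zero. T²
    values above 1 are reported as-is: with social effects the heritable
    variance an individual commands can exceed the phenotypic variance of a
    single record.
    """
    vc, cov, model = fit.vc, fit.cov, fit.model
    tbv = total_breeding_variance(vc, n)
    p_var = phenotypic_variance(vc, n, model)
    out = DerivedParameters(
        n=n,
        model=model,
        sigma2_TBV=tbv,
        sigma2_P=p_var,
        T2=tbv / p_var if p_var > 0 else float("nan"),
        h2=vc.sigma2_AD / p_var if p_var > 0 else float("nan"),
        r_AS_AD=direct_social_correlation(vc),
        se_sigma2_TBV=_delta_se(lambda v: total_breeding_variance(v, n), vc, cov),
        se_sigma2_P=_delta_se(lambda v: phenotypic_variance(v, n, model), vc, cov),
        se_T2=_delta_se(
            lambda v: total_breeding_variance(v, n) / phenotypic_variance(v, n, model),
            vc,
            cov,
        )
        if p_var > 0
        else float("nan"),
        se_h2=_delta_se(
            lambda v: v.sigma2_AD / phenotypic_variance(v, n, model), vc, cov
        )
        if p_var > 0
        else float("nan"),
        se_r_AS_AD=_delta_se(direct_social_correlation, vc, cov)
        if vc.sigma2_AD > 0 and vc.sigma2_AS > 0
        else float("nan"),
        shares=partition(vc, n) if total_breeding_variance(vc, n) > 0 else None,
    )
    return out


def parametric_bootstrap_se(
    model_fit: ModelFit,
    mm,
    Ainv,
    ped,
    n: int = DEFAULT_GROUP_SIZE,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap SEs for the derived parameters by refitting simulated data.

    The first-order delta method is unreliable when components sit near the
    boundary (the situation for most social variances in a design of this
    size). This resamples instead: simulate phenotypes from the fitted model
    — breeding values through the pedigree with the estimated G, environment
    and residual effects at their estimated variances — refit, re-derive, and
    report the spread over replicates. Expensive (one REML fit per
    replicate); intended for final reporting, not routine use.
    """
    from .reml import fit as reml_fit, FitOptions
    from .simulate import simulate_breeding_values

    rng = np.random.default_rng(seed)
    vc = model_fit.vc
    Xb = mm.X @ model_fit.beta
    stats = {k: [] for k in ("sigma2_TBV", "sigma2_P", "T2", "h2", "r_AS_AD")}
    opts = FitOptions(compute_cov=False, polish=False)
    for _ in range(n_boot):
        u = simulate_breeding_values(ped, vc.G, rng)
        y = Xb + mm.Z_D @ u[:, 0]
        if mm.Z_S is not None:
            y = y + mm.Z_S @ u[:, 1]
        if mm.W_c is not None:
            y = y + mm.W_c @ rng.normal(0, np.sqrt(vc.sigma2_c), mm.W_c.shape[1])
        if mm.W_t is not None:
            y = y + mm.W_t @ rng.normal(0, np.sqrt(vc.sigma2_t), mm.W_t.shape[1])
        y = y + rng.normal(0, np.sqrt(vc.sigma2_e), mm.n_obs)
        mm_b = dataclasses.replace(mm, y=np.asarray(y))
        fb = reml_fit(mm_b, Ainv, model_fit.model, opts)
        dp = derive(fb, n)
        for k in stats:
            stats[k].append(getattr(dp, k))
    rows = []
    for k, vals in stats.items():
        arr = np.asarray(vals, dtype=float)
        ok = np.isfinite(arr)
        rows.append(
            {
                "parameter": k,
                "bootstrap_se": float(arr[ok].std(ddof=1)) if ok.sum() > 1 else np.nan,
                "n_effective": int(ok.sum()),
            }
        )
    return pd.DataFrame(rows)


def fit_report(fit: ModelFit, n: int = DEFAULT_GROUP_SIZE) -> pd.DataFrame:
    """Tidy table of variance components and derived parameters with SEs."""
    rows = []
    for comp in COMPONENTS:
        if fit.model == "conventional" and comp in ("sigma2_AS", "sigma_ADS"):
            continue
        est = getattr(fit.vc, comp)
        rows.append(
            {
                "parameter": comp,
                "estimate": est,
                "se": fit.se(comp),
                "boundary": fit.boundary.get(comp, False),
            }
        )
    df = pd.DataFrame(rows)
    dp = derive(fit, n)
    extra = dp.to_frame()[["parameter", "estimate", "se"]]
    extra["boundary"] = False
    df = pd.concat([df, extra], ignore_index=True)
    df["model"] = fit.model
    df["n"] = n
    return df
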