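import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codsge import (
    direct_social_correlation,
    derive,
    heritability,
    partition,
    phenotypic_variance,
    t_squared,
    total_breeding_variance,
)
from codsge.reml import COMPONENTS, ModelFit, VarianceComponents


def _fit_with(vc: VarianceComponents, cov=None, model="social") -> ModelFit:
    return ModelFit(
        model=model,
        vc=vc,
        beta=np.zeros(1),
        x_labels=["intercept"],
        loglik=0.0,
        cov=np.zeros((6, 6)) if cov is None else cov,
        converged=True,
        n_iter=1,
        boundary={c: False for c in COMPONENTS},
        n_obs=100,
    )


def _vc_strategy():
    pos = st.floats(min_value=1e-3, max_value=100.0, allow_nan=False)
    return st.builds(
        lambda ad, as_, r, c, t, e: VarianceComponents(
            sigma2_AD=ad,
            sigma2_AS=as_,
            sigma_ADS=r * math.sqrt(ad * as_),
            sigma2_c=c,
            sigma2_t=t,
            sigma2_e=e,
        ),
        ad=pos,
        as_=pos,
        r=st.floats(min_value=-0.99, max_value=0.99),
        c=pos,
        t=pos,
        e=pos,
    )


class TestTotalBreedingVariance:
    def test_reduces_to_direct_variance_without_social_terms(self):
        vc = VarianceComponents(sigma2_AD=7.3, sigma2_e=1.0)
        assert total_breeding_variance(vc, 21) == pytest.approx(7.3)

    def test_equals_variance_of_total_breeding_values(self, rng):
        """σ²_TBV is literally Var(a_D + (n−1)·a_S) over unrelated animals."""
        vc = VarianceComponents(6.13, 0.03, 0.23, sigma2_e=1.0)
        L = np.linalg.cholesky(vc.G)
        draws = (L @ rng.standard_normal((2, 100_000))).T
        tbv = draws[:, 0] + 20 * draws[:, 1]
        assert np.var(tbv) == pytest.approx(total_breeding_variance(vc, 21), rel=0.02)

    def test_group_size_must_be_at_least_two(self):
        with pytest.raises(ValueError):
            total_breeding_variance(VarianceComponents(1.0), n=1)


class TestPhenotypicVariance:
    def test_residual_only(self):
        assert phenotypic_variance(VarianceComponents(0.0, sigma2_e=1.0), 21) == 1.0

    def test_conventional_model_drops_social_term(self):
        vc = VarianceComponents(2.0, 0.5, 0.1, 1.0, 1.0, 1.0)
        assert phenotypic_variance(vc, 21, "conventional") == pytest.approx(5.0)
        assert phenotypic_variance(vc, 21, "social") == pytest.approx(5.0 + 20 * 0.5)

    @given(vc=_vc_strategy(), scale=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_of_degree_one(self, vc, scale):
        scaled = VarianceComponents.from_array(scale * vc.as_array())
        assert phenotypic_variance(scaled, 21) == pytest.approx(
            scale * phenotypic_variance(vc, 21), rel=1e-9
        )


class TestRatios:
    @given(vc=_vc_strategy())
    @settings(max_examples=50, deadline=None)
    def test_t2_equals_h2_without_social_terms(self, vc):
        no_social = VarianceComponents(
            vc.sigma2_AD, 0.0, 0.0, vc.sigma2_c, vc.sigma2_t, vc.sigma2_e
        )
        assert t_squared(no_social, 21) == pytest.approx(
            heritability(no_social, 21), rel=1e-12
        )

    @given(vc=_vc_strategy())
    @settings(max_examples=50, deadline=None)
    def test_shares_sum_to_hundred(self, vc):
        assert sum(partition(vc, 21)) == pytest.approx(100.0, abs=0.1)

    def test_correlation_zero_for_diagonal_G(self):
        assert direct_social_correlation(VarianceComponents(3.0, 2.0, 0.0)) == 0.0

    def test_correlation_undefined_at_boundary(self):
        assert math.isnan(direct_social_correlation(VarianceComponents(3.0, 0.0, 0.0)))

    @given(vc=_vc_strategy())
    @settings(max_examples=50, deadline=None)
    def test_correlation_bounded_for_psd_G(self, vc):
        assert abs(direct_social_correlation(vc)) <= 1.0 + 1e-9


class TestDeltaMethod:
    def test_h2_se_matches_hand_computed_gradient(self):
        # h² = σ²_AD/(σ²_AD + σ²_e) with independent sampling errors:
        # Var(h²) ≈ (∂h/∂AD)²·v1 + (∂h/∂e)²·v2
        vc = VarianceComponents(sigma2_AD=4.0, sigma2_e=6.0)
        v1, v2 = 0.9, 1.3
        cov = np.zeros((6, 6))
        cov[0, 0], cov[5, 5] = v1, v2
        f = _fit_with(vc, cov, model="conventional")
        dp = derive(f, n=21)
        sp = 10.0
        g_ad = (sp - 4.0) / sp**2
        g_e = -4.0 / sp**2
        expected = math.sqrt(g_ad**2 * v1 + g_e**2 * v2)
        assert dp.se_h2 == pytest.approx(expected, rel=1e-3)

    def test_tbv_se_linear_exact(self):
        # σ²_TBV is linear in the components, so the delta method is exact:
        # Var = a'Σa with a = (1, (n−1)², 2(n−1), 0, 0, 0)
        vc = VarianceComponents(6.0, 0.05, 0.2, 0.5, 0.1, 4.0)
        rng = np.random.default_rng(0)
        B = rng.standard_normal((6, 6)) * 0.1
        cov = B @ B.T
        f = _fit_with(vc, cov)
        dp = derive(f, n=21)
        a = np.array([1.0, 400.0, 40.0, 0.0, 0.0, 0.0])
        assert dp.se_sigma2_TBV == pytest.approx(math.sqrt(a @ cov @ a), rel=1e-3)

    def test_derive_reports_undefined_correlation_at_boundary(self):
        vc = VarianceComponents(6.0, 0.0, 0.0, 0.5, 0.1, 4.0)
        dp = derive(_fit_with(vc), n=21)
        assert math.isnan(dp.r_AS_AD)
        assert dp.T2 == pytest.approx(dp.h2)


def test_parametric_bootstrap_se_smoke(small_sim):
    """Bootstrap SEs refit simulated replicates of the fitted model and give
    finite, positive spreads for the derived parameters."""
    from codsge import fit, parametric_bootstrap_se
    from codsge.reml import FitOptions

    f = fit(
        small_sim["mm_social"],
        small_sim["Ainv"],
        "social",
        FitOptions(compute_cov=False, polish=False),
    )
    df = parametric_bootstrap_se(
        f,
        small_sim["mm_social"],
        small_sim["Ainv"],
        small_sim["res"].ped,
        n_boot=4,
        seed=3,
    )
    assert set(df["parameter"]) == {"sigma2_TBV", "sigma2_P", "T2", "h2", "r_AS_AD"}
    tbv = df.set_index("parameter").loc["sigma2_TBV"]
    assert tbv["n_effective"] == 4 and np.isfinite(tbv["bootstrap_se"]) and tbv["bootstrap_se"] > 0
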