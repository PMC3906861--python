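import dataclasses
import math

import numpy as np
import pytest
from scipy import optimize

from codsge import Pedigree, build_A_inverse, fit, lrt, reml_loglik
from codsge.design import ModelMatrices
from codsge.reml import COMPONENTS, FitOptions, ModelFit, VarianceComponents, _Workspace
from conftest import TRUE_VC
from oracles import anova_halfsib_sigma2A, dense_reml_loglik

THETAS = [
    TRUE_VC,
    VarianceComponents(2.0, 0.1, 0.2, 1.0, 0.5, 3.0),
    VarianceComponents(5.0, 0.001, -0.05, 0.01, 2.0, 1.0),
]


@pytest.fixture(scope="session")
def small_fits(small_sim):
    opts = FitOptions()
    fs = fit(small_sim["mm_social"], small_sim["Ainv"], "social", opts)
    fc = fit(small_sim["mm_conventional"], small_sim["Ainv"], "conventional", opts)
    return fs, fc


class TestLoglik:
    @pytest.mark.parametrize("theta", THETAS)
    def test_matches_dense_formula(self, small_sim, theta):
        sparse_ll = reml_loglik(theta, small_sim["mm_social"], small_sim["Ainv"])
        dense_ll = dense_reml_loglik(theta, small_sim["mm_social"], small_sim["A"])
        assert sparse_ll == pytest.approx(dense_ll, abs=1e-6)

    def test_zero_variance_component_leaves_loglik_unchanged(self, small_sim):
        mm = small_sim["mm_social"]
        theta = dataclasses.replace(TRUE_VC, sigma2_c=0.0)
        with_block = reml_loglik(theta, mm, small_sim["Ainv"])
        mm_noc = dataclasses.replace(mm, W_c=None)
        without_block = reml_loglik(theta, mm_noc, small_sim["Ainv"])
        assert with_block == pytest.approx(without_block, abs=1e-8)

    def test_row_permutation_invariance(self, small_sim, rng):
        mm = small_sim["mm_social"]
        perm = rng.permutation(mm.n_obs)
        mm_p = dataclasses.replace(
            mm,
            y=mm.y[perm],
            X=mm.X[perm],
            Z_D=mm.Z_D[perm],
            Z_S=mm.Z_S[perm],
            W_c=mm.W_c[perm],
            W_t=mm.W_t[perm],
            tank_sizes=mm.tank_sizes[perm],
        )
        a = reml_loglik(TRUE_VC, mm, small_sim["Ainv"])
        b = reml_loglik(TRUE_VC, mm_p, small_sim["Ainv"])
        assert a == pytest.approx(b, abs=1e-8)

    def test_residual_only_profile_optimum_is_rss(self, small_sim):
        """With no random effects the profiled REML variance is the OLS
        residual variance RSS/(N − rank X)."""
        mm = dataclasses.replace(
            small_sim["mm_social"], Z_S=None, W_c=None, W_t=None
        )
        ws = _Workspace(mm, small_sim["Ainv"])
        y, X = mm.y, mm.X
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        target = rss / (len(y) - X.shape[1])

        def nll(log_s2):
            theta = VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, math.exp(log_s2))
            return -ws.loglik(theta)

        res = optimize.minimize_scalar(nll, bounds=(-5, 5), method="bounded")
        assert math.exp(res.x) == pytest.approx(target, rel=1e-5)


class TestFit:
    def test_social_not_below_conventional(self, small_fits):
        fs, fc = small_fits
        assert fs.loglik >= fc.loglik - 1e-4

    def test_boundary_flags_are_exact_zeros(self, small_fits):
        for f in small_fits:
            for comp, flagged in f.boundary.items():
                if flagged:
                    assert getattr(f.vc, comp) == 0.0
            f.vc.validate()

    def test_curvature_symmetric_psd_at_interior(self, small_fits):
        fs, _ = small_fits
        cov = fs.cov
        assert np.allclose(cov, cov.T, atol=1e-10)
        free = [k for k in range(6) if cov[k, k] != 0]
        eigs = np.linalg.eigvalsh(cov[np.ix_(free, free)])
        assert eigs.min() > -1e-8 * max(eigs.max(), 1.0)

    def test_halfsib_reml_equals_anova_on_balanced_data(self):
        """Balanced paternal half-sib design: animal-model REML reproduces the
        expected-mean-squares (ANOVA) estimator exactly on balanced data."""
        rng = np.random.default_rng(11)
        n_sires, n_prog = 40, 10
        sigma2_A, sigma2_e = 4.0, 6.0
        entries = [(f"s{j}", None, None) for j in range(n_sires)]
        sire_idx = np.repeat(np.arange(n_sires), n_prog)
        for k, j in enumerate(sire_idx):
            entries.append((f"p{k}", f"s{j}", None))
        ped = Pedigree.from_entries(entries)
        a_sire = rng.normal(0, np.sqrt(sigma2_A), n_sires)
        a_prog = 0.5 * a_sire[sire_idx] + rng.normal(
            0, np.sqrt(0.75 * sigma2_A), len(sire_idx)
        )
        y = 10.0 + a_prog + rng.normal(0, np.sqrt(sigma2_e), len(sire_idx))

        from scipy import sparse as sp

        n = len(y)
        own = np.array([ped.index[f"p{k}"] for k in range(n)])
        mm = ModelMatrices(
            y=y,
            X=np.ones((n, 1)),
            Z_D=sp.csr_matrix((np.ones(n), (np.arange(n), own)), shape=(n, len(ped))),
            Z_S=None,
            W_c=None,
            W_t=None,
            obs_ids=[f"p{k}" for k in range(n)],
            x_labels=["intercept"],
            c_levels=[],
            t_levels=[],
            tank_sizes=None,
        )
        f = fit(mm, build_A_inverse(ped), "conventional")
        anova_A, _ = anova_halfsib_sigma2A(y, sire_idx)
        assert anova_A > 0  # interior case, where the equivalence is exact
        assert f.vc.sigma2_AD == pytest.approx(anova_A, rel=5e-3)


def _stub_fit(loglik: float, model: str) -> ModelFit:
    return ModelFit(
        model=model,
        vc=VarianceComponents(1.0),
        beta=np.zeros(1),
        x_labels=["intercept"],
        loglik=loglik,
        cov=np.zeros((6, 6)),
        converged=True,
        n_iter=1,
        boundary={c: False for c in COMPONENTS},
        n_obs=10,
    )


class TestLRT:
    @pytest.mark.parametrize(
        "delta,p_rounded",
        [(1.45, 0.23), (0.04, 0.96), (2.12, 0.12), (0.0, 1.0)],
    )
    def test_chi2_2df_p_equals_exp_minus_delta(self, delta, p_rounded):
        r = lrt(_stub_fit(-100.0, "conventional"), _stub_fit(-100.0 + delta, "social"))
        assert r.df == 2
        assert r.chi2 == pytest.approx(2 * delta)
        assert r.p == pytest.approx(math.exp(-delta), rel=1e-12)
        assert round(r.p, 2) == p_rounded

    def test_negative_delta_warns_and_floors(self):
        with pytest.warns(RuntimeWarning, match="refitting"):
            r = lrt(_stub_fit(-100.0, "conventional"), _stub_fit(-100.5, "social"))
        assert r.chi2 == 0.0 and r.p == 1.0

    def test_mixture_correction_is_smaller(self):
        r_naive = lrt(_stub_fit(-100.0, "conventional"), _stub_fit(-98.0, "social"))
        r_mix = lrt(
            _stub_fit(-100.0, "conventional"), _stub_fit(-98.0, "social"), mixture=True
        )
        assert r_mix.p < r_naive.p
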