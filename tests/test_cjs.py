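"""CJS likelihood identities, fitting, and estimability."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from wintercmr.cjs import chi_tail, count_estimable, fit, individual_loglik, real_estimates, total_loglik
from wintercmr.design import CJSData, DesignSpec, build_design
from wintercmr.marray import build_marray, fit_marray, marray_loglik
from wintercmr.synthetic import simulate_histories

from conftest import make_cjs_data


class TestChiTail:
    def test_certain_redetection(self):
        assert chi_tail([1.0], [1.0])[0] == 0.0

    def test_hand_recursion_two_occasions(self):
        assert chi_tail([0.8], [0.6])[0] == pytest.approx(0.52)

    def test_dead_fish_never_seen(self):
        chi = chi_tail([0.0, 0.0, 0.0], [0.5, 0.5, 0.5])
        assert np.all(chi == 1.0)

    @given(
        phi=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
        p=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_is_a_probability(self, phi, p):
        k = min(len(phi), len(p))
        chi = chi_tail(phi[:k], p[:k])
        assert np.all((chi >= 0) & (chi <= 1))


class TestIndividualLoglik:
    def test_detected_next_occasion(self):
        assert np.exp(individual_loglik([1, 1], [0.8], [0.6])) == pytest.approx(0.48)

    def test_never_seen_equals_chi(self):
        assert np.exp(individual_loglik([1, 0], [0.8], [0.6])) == pytest.approx(0.52)

    @pytest.mark.parametrize("T", [2, 3, 4, 5, 6])
    def test_probability_conservation_exhaustive(self, T):
        """Sum over all 2^(T-1) post-release histories equals one."""
        rng = np.random.default_rng(T)
        phi = rng.uniform(0.05, 0.95, T - 1)
        p = rng.uniform(0.05, 0.95, T - 1)
        total = sum(
            np.exp(individual_loglik(np.array([1, *bits]), phi, p))
            for bits in itertools.product([0, 1], repeat=T - 1)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_total_matches_per_individual_sum(self):
        data = make_cjs_data(n=40, T=7, seed=2)
        dm = build_design(DesignSpec.parse("{phi(1)p(1)}"), data)
        beta = np.array([0.7, -0.2])
        phi = np.full(6, expit(0.7))
        p = np.full(6, expit(-0.2))
        direct = sum(individual_loglik(h, phi, p) for h in data.histories)
        assert total_loglik(beta, data, dm) == pytest.approx(direct, abs=1e-9)


class TestMArrayEquivalence:
    def test_loglik_identity_without_covariates(self):
        """Individual-level and m-array likelihoods agree at arbitrary parameters."""
        rng = np.random.default_rng(8)
        data = make_cjs_data(n=250, T=10, phi=0.85, p=0.45, seed=8)
        dm = build_design(DesignSpec.parse("{phi(t)p(1)}"), data)
        beta = rng.normal(0, 0.7, dm.n_params)
        phi = expit(dm.X_phi[0] @ beta[:9])
        p = expit(dm.X_p[0] @ beta[9:])
        arr = build_marray(data.histories)
        assert total_loglik(beta, data, dm) == pytest.approx(
            marray_loglik(arr, phi, p), rel=1e-10
        )

    def test_fitted_estimates_agree(self):
        data = make_cjs_data(n=400, T=8, phi=0.9, p=0.55, seed=9)
        fi = fit("{phi(1)p(1)}", data, seed=0)
        fm = fit_marray("{phi(1)p(1)}", data, seed=0)
        assert np.allclose(fi.beta, fm.beta, atol=1e-4)
        assert fi.log_likelihood == pytest.approx(fm.log_likelihood, abs=1e-6)

    def test_grouped_marray_requires_shared_rows(self):
        data = make_cjs_data(n=30, T=5, seed=1)
        cov = CJSData(
            histories=data.histories,
            groups=data.groups,
            covariates=pd.DataFrame({"cond": np.linspace(0.8, 1.2, 30)}),
        )
        with pytest.raises(ValueError, match="individual covariates"):
            fit_marray("{phi(cond)p(1)}", cov, compute_hessian=False)


class TestFit:
    def test_recovers_constant_parameters(self):
        data = make_cjs_data(n=1500, T=10, phi=0.9, p=0.6, seed=3)
        f = fit("{phi(1)p(1)}", data, seed=0)
        phi_hat, p_hat = expit(f.beta)
        assert phi_hat == pytest.approx(0.9, abs=0.03)
        assert p_hat == pytest.approx(0.6, abs=0.04)
        assert f.converged and f.n_estimable == 2

    def test_likelihood_at_optimum_beats_truth(self):
        data = make_cjs_data(n=300, T=8, phi=0.85, p=0.5, seed=4)
        f = fit("{phi(1)p(1)}", data, seed=0)
        truth = np.array([logit(0.85), logit(0.5)])
        assert f.log_likelihood >= total_loglik(truth, data, f.dm) - 1e-8

    def test_saturated_detection_boundary_flagged(self):
        rng = np.random.default_rng(5)
        H = simulate_histories(np.full((200, 5), 0.95), np.ones((200, 5)), rng)
        data = CJSData(histories=H, groups=np.array(["sculpin"] * 200))
        f = fit("{phi(1)p(1)}", data, seed=0)
        assert expit(f.beta[1]) > 0.999  # p estimate driven to the boundary

    def test_covariate_shift_leaves_real_parameters_unchanged(self):
        """Logit-link invariance: shifting a covariate only moves the intercept."""
        rng = np.random.default_rng(6)
        n, T = 400, 8
        cond = rng.normal(1.0, 0.15, n)
        phi = expit(1.2 + 1.5 * (cond[:, None] - 1.0)) * np.ones((n, T - 1))
        p = np.full((n, T - 1), 0.6)
        H = simulate_histories(phi, p, rng)
        base = CJSData(
            histories=H,
            groups=np.array(["sculpin"] * n),
            covariates=pd.DataFrame({"cond": cond}),
        )
        shifted = CJSData(
            histories=H,
            groups=base.groups,
            covariates=pd.DataFrame({"cond": cond + 5.0}),
        )
        f0 = fit("{phi(cond)p(1)}", base, seed=0)
        f1 = fit("{phi(cond)p(1)}", shifted, seed=0)
        dm = f0.dm
        phi0 = expit(np.einsum("ntq,q->nt", dm.X_phi, f0.dm.split(f0.beta)[0]))
        phi1 = expit(np.einsum("ntq,q->nt", f1.dm.X_phi, f1.dm.split(f1.beta)[0]))
        assert np.allclose(phi0, phi1, atol=1e-6)
        # slope unchanged, intercept absorbs the shift
        assert f0.beta[1] == pytest.approx(f1.beta[1], abs=1e-4)


class TestEstimability:
    def test_constant_model_rank_two(self):
        data = make_cjs_data(n=200, T=6, seed=7)
        assert count_estimable(fit("{phi(1)p(1)}", data, seed=0)) == 2

    @pytest.mark.parametrize("T", [5, 6])
    def test_time_dependent_rank_is_2T_minus_3(self, T):
        """Classical CJS deficiency: terminal phi and p enter only as a product."""
        rng = np.random.default_rng(T + 10)
        n = 900
        phi = np.tile(rng.uniform(0.7, 0.9, T - 1), (n, 1))
        p = np.tile(rng.uniform(0.4, 0.7, T - 1), (n, 1))
        H = simulate_histories(phi, p, rng)
        data = CJSData(histories=H, groups=np.array(["sculpin"] * n))
        f = fit("{phi(t)p(t)}", data, seed=0)
        assert f.n_estimable == 2 * T - 3
        assert f.terminal_confounded

    def test_rank_equals_thresholded_eigencount(self):
        data = make_cjs_data(n=300, T=6, seed=12)
        f = fit("{phi(t)p(t)}", data, seed=0)
        w = np.linalg.eigvalsh(0.5 * (f.hessian + f.hessian.T))
        expected = int(np.sum(w > f.eig_threshold_rel * w.max()))
        assert f.n_estimable == expected


def test_real_estimates_shape_and_range():
    data = make_cjs_data(n=300, T=6, phi=0.85, p=0.5, seed=13)
    f = fit("{phi(1)p(t)}", data, seed=0)
    est = real_estimates(f)
    assert set(est["parameter"]) == {"phi", "p"}
    assert ((est["estimate"] >= 0) & (est["estimate"] <= 1)).all()
    assert (est["se"] >= 0).all()
    phi_rows = est[est["parameter"] == "phi"]
    assert len(phi_rows) == 5
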