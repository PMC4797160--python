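"""QAICc arithmetic, ranking invariants, and median c-hat behavior."""

import numpy as np
import pytest
from scipy.special import expit

from wintercmr.cjs import fit
from wintercmr.design import CJSData
from wintercmr.marray import fit_marray
from wintercmr.selection import (
    ModelResult,
    adjust_for_overdispersion,
    median_chat,
    qaicc,
    rank_models,
)
from wintercmr.synthetic import simulate_histories

from conftest import make_cjs_data


class TestQaicc:
    def test_hand_arithmetic(self):
        assert qaicc(-100.0, 5, 100, 1.0) == pytest.approx(200 + 10 + 60 / 94, abs=1e-6)

    def test_reduces_to_aicc_at_chat_one(self):
        assert qaicc(-50.0, 3, 40, 1.0) == pytest.approx(100 + 6 + 24 / 36)

    def test_chat_shrinks_deviance_term(self):
        lo, hi = qaicc(-100.0, 5, 100, 1.0), qaicc(-100.0, 5, 100, 1.5)
        assert hi < lo

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            qaicc(-10.0, 10, 11)

    def test_chat_below_one_rejected(self):
        with pytest.raises(ValueError):
            qaicc(-10.0, 2, 100, 0.8)


def results_from_deltas(deltas):
    # synthetic results whose QAICc values differ by the requested deltas
    return [ModelResult(name=f"m{i}", log_likelihood=-d / 2.0, K=1, n_eff=10_000)
            for i, d in enumerate(deltas)]


class TestRankModels:
    def test_single_model_weight_one(self):
        t = rank_models(results_from_deltas([0.0]))
        assert t["weight"].iloc[0] == pytest.approx(1.0)

    def test_two_model_closed_form(self):
        t = rank_models(results_from_deltas([0.0, 2.0]))
        assert t["weight"].tolist() == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_three_model_field_table(self):
        """Deltas 0 / 1.68 / 10.34 give weights ~0.6953 / 0.3007 / 0.0040."""
        t = rank_models(results_from_deltas([0.0, 1.68, 10.34]))
        assert t["weight"].tolist() == pytest.approx([0.6953, 0.3007, 0.0040], abs=5e-4)
        assert t["model_likelihood"].iloc[1] == pytest.approx(
            t["weight"].iloc[1] / t["weight"].iloc[0], rel=1e-9
        )

    def test_weights_sum_to_one_and_shift_invariance(self):
        rng = np.random.default_rng(0)
        lls = rng.uniform(-500, -400, 6)
        res = [ModelResult(f"m{i}", ll, K=3, n_eff=500) for i, ll in enumerate(lls)]
        shifted = [ModelResult(f"m{i}", ll + 123.4, K=3, n_eff=500) for i, ll in enumerate(lls)]
        t0, t1 = rank_models(res), rank_models(shifted)
        assert t0["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(t0["weight"], t1["weight"])
        assert list(t0["model"]) == list(t1["model"])

    def test_qaicc_ordering_matches_aicc_at_chat_one(self):
        rng = np.random.default_rng(1)
        res = [ModelResult(f"m{i}", rng.uniform(-300, -200), K=int(k), n_eff=400)
               for i, k in enumerate([2, 5, 9])]
        order_q = list(rank_models(res)["model"])
        aicc = {r.name: -2 * r.log_likelihood + 2 * r.K + 2 * r.K * (r.K + 1) / (400 - r.K - 1)
                for r in res}
        order_a = sorted(aicc, key=aicc.get)
        assert order_q == order_a


class TestAdjustForOverdispersion:
    def test_identity_at_one(self):
        data = make_cjs_data(n=300, T=6, seed=2)
        f = fit("{phi(1)p(1)}", data, seed=0)
        assert np.allclose(adjust_for_overdispersion(f, 1.0).se, f.se)

    def test_se_inflated_by_sqrt_chat(self):
        data = make_cjs_data(n=300, T=6, seed=2)
        f = fit("{phi(1)p(1)}", data, seed=0)
        adj = adjust_for_overdispersion(f, 1.21)
        assert np.allclose(adj.se, 1.1 * f.se, rtol=1e-12)

    def test_below_one_floored_with_warning(self):
        data = make_cjs_data(n=200, T=5, seed=3)
        f = fit("{phi(1)p(1)}", data, seed=0)
        with pytest.warns(UserWarning, match="floored"):
            adj = adjust_for_overdispersion(f, 0.7)
        assert np.allclose(adj.se, f.se)


def _grouped_data(seed, T=14, overdispersion=1):
    """Study-scale grouped data straight from an ice-driven CJS model.

    Biweekly occasions, three groups at resident sample sizes, detection
    declining with a shared ice covariate — the structure the GOF procedure
    is run on in practice.  T=14 keeps the m-array cell count (hence the
    degrees of freedom of the deviance statistic) large enough for a stable
    calibration.
    """
    rng = np.random.default_rng(seed)
    ice = np.linspace(0.02, 0.45, T - 1)
    groups, hists = [], []
    for g, (n, a, b) in {
        "sculpin": (145, 0.9, -4.0),
        "juvenile_trout": (42, 0.8, -2.5),
        "adult_trout": (110, 2.2, -1.0),
    }.items():
        n_unique = max(1, n // overdispersion)
        p = expit(a + b * ice)
        H = simulate_histories(
            np.full((n_unique, T - 1), 0.97), np.tile(p, (n_unique, 1)), rng
        )
        H = np.repeat(H, overdispersion, axis=0)
        hists.append(H)
        groups.extend([g] * len(H))
    return CJSData(
        histories=np.vstack(hists),
        groups=np.array(groups),
        time_covariates={"ice": ice},
    )


class TestMedianChat:
    def test_null_calibration_across_seeds(self):
        """Data straight from the model: c-hat stays near 1.

        A single run inherits the sampling noise of the observed
        deviance/df statistic (sd ~ sqrt(2/df)), so each estimate is only
        loosely bounded while the median over three independent datasets
        must sit in the calibration band.
        """
        ests = []
        for seed in (1, 2, 3):
            est = median_chat("{phi(g)p(g x t)}", _grouped_data(seed),
                              levels=(1.0, 1.25, 1.5, 1.75, 2.0), n_rep=30, seed=seed)
            assert 1.0 <= est.c_hat <= 1.3
            ests.append(est.c_hat)
        assert 0.9 <= float(np.median(ests)) <= 1.1

    def test_clustered_data_detected_as_overdispersed(self):
        """Duplicating every individual doubles the variance; c-hat responds."""
        data = _grouped_data(7, overdispersion=2)
        est = median_chat("{phi(g)p(g x t)}", data, levels=(1.0, 1.5, 2.0, 2.5),
                          n_rep=30, seed=7)
        assert est.c_hat > 1.3

    def test_rejects_individual_covariates(self):
        import pandas as pd

        data = make_cjs_data(n=40, T=5, seed=5)
        cov = CJSData(
            histories=data.histories,
            groups=data.groups,
            covariates=pd.DataFrame({"cond": np.linspace(0.8, 1.2, 40)}),
        )
        with pytest.raises(ValueError, match="individual covariates"):
            median_chat("{phi(cond)p(1)}", cov, n_rep=2, seed=0)
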