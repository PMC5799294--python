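"""Decomposition model: Gaussian oracle, identifiability, recovery, testing."""

import numpy as np
import pandas as pd
import pytest

from txdecomp.model import (
    DecompositionModel,
    DecompositionResults,
    component_fraction,
    differential_components,
    fit_joint,
    grid_select_hyperparameters,
)
from txdecomp.rw1 import rw1_structure, sample_rw1
from txdecomp.stats import bh_adjust


def gaussian_penalised_solve(Y, tau_rw, tau_iid, tau_obs, alpha_prec=1e-6):
    """Independent oracle: dense KKT solve of the penalised normal equations.

    Minimises tau_obs * sum_ir (y_ir - alpha - PD_i - PI_i)^2 / 2 plus the
    RW1 and iid penalties, subject to sum(PD) = 0, by direct linear algebra.
    """
    n, reps = Y.shape
    S, _ = rw1_structure(n)
    S = S.toarray()
    Qp = np.zeros((2 * n + 1, 2 * n + 1))
    Qp[:n, :n] = tau_rw * S
    Qp[n : 2 * n, n : 2 * n] = tau_iid * np.eye(n)
    Qp[2 * n, 2 * n] = alpha_prec
    M = np.zeros((n, 2 * n + 1))
    M[:, :n] = np.eye(n)
    M[:, n : 2 * n] = np.eye(n)
    M[:, 2 * n] = 1.0
    A = reps * tau_obs * M.T @ M + Qp
    b = tau_obs * M.T @ Y.sum(axis=1)
    a = np.zeros(2 * n + 1)
    a[:n] = 1.0
    K = np.block([[A, a[:, None]], [a[None, :], np.zeros((1, 1))]])
    sol = np.linalg.solve(K, np.concatenate([b, [0.0]]))
    return sol[:n], sol[n : 2 * n], sol[2 * n]


def _fake_results(pd_vals, pi_vals, pd_sd=None, pi_sd=None):
    pd_vals = np.asarray(pd_vals, dtype=float)
    pi_vals = np.asarray(pi_vals, dtype=float)
    n = pd_vals.size
    model = DecompositionModel(np.ones((max(n, 2), 1)), family="gaussian")
    return DecompositionResults(
        model=model, alpha=0.0, alpha_sd=0.1,
        pd=pd_vals, pd_sd=np.full(n, 0.1) if pd_sd is None else np.asarray(pd_sd, float),
        pi=pi_vals, pi_sd=np.full(n, 0.1) if pi_sd is None else np.asarray(pi_sd, float),
        tau_rw=1.0, tau_iid=1.0, k=1.0, p0=0.0, log_marginal=0.0,
        n_iter=1, converged=True,
    )


class TestGaussianOracle:
    def test_fit_matches_direct_sparse_solve(self):
        """Gaussian-likelihood fit equals the exact penalised linear solve."""
        rng = np.random.default_rng(1)
        n = 200
        Y = (
            1.0
            + sample_rw1(n, 1.0, rng)[:, None]
            + rng.normal(0, 0.5, (n, 1))
            + rng.normal(0, 0.3, (n, 3))
        )
        tau_rw, tau_iid, tau_obs = 2.0, 4.0, 1 / 0.09
        model = DecompositionModel(Y, family="gaussian", tau_obs=tau_obs)
        res = model.fit(tau_rw=tau_rw, tau_iid=tau_iid)
        pd_o, pi_o, al_o = gaussian_penalised_solve(Y, tau_rw, tau_iid, tau_obs)
        assert np.max(np.abs(res.pd - pd_o)) < 1e-6
        assert np.max(np.abs(res.pi - pi_o)) < 1e-6
        assert abs(res.alpha - al_o) < 1e-6

    def test_constant_observations_put_everything_in_the_intercept(self):
        Y = np.full((50, 3), 2.5)
        model = DecompositionModel(Y, family="gaussian")
        res = model.fit(tau_rw=1.0, tau_iid=1.0)
        assert np.max(np.abs(res.pd)) < 1e-3
        assert np.max(np.abs(res.pi)) < 1e-3
        assert res.alpha == pytest.approx(2.5, abs=1e-3)


class TestIdentifiabilityAndMonotonicity:
    def test_pd_sums_to_zero(self, recovery_fit):
        assert recovery_fit["results"].pd.sum() == pytest.approx(0.0, abs=1e-6)

    def test_posterior_sds_nonnegative(self, recovery_fit):
        res = recovery_fit["results"]
        assert np.all(res.pd_sd >= 0) and np.all(res.pi_sd >= 0)

    def test_total_variation_decreases_with_tau_rw(self):
        """A smoother RW1 prior never roughens the fitted PD."""
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, (120, 2)) + sample_rw1(120, 0.5, rng)[:, None]
        model = DecompositionModel(Y, family="gaussian")
        tvs = []
        for tau in (0.1, 1.0, 10.0, 100.0):
            res = model.fit(tau_rw=tau, tau_iid=2.0, compute_sd=False)
            tvs.append(np.sum(np.abs(np.diff(res.pd))))
        assert all(a >= b - 1e-9 for a, b in zip(tvs, tvs[1:]))


class TestRecovery:
    def test_pd_track_recovered(self, recovery_fit):
        r = np.corrcoef(recovery_fit["results"].pd, recovery_fit["truth"].pd)[0, 1]
        assert r >= 0.8

    def test_hyperparameters_within_factor_three(self, recovery_fit):
        res = recovery_fit["results"]
        assert 1 / 3 <= res.tau_rw / 1.0 <= 3
        assert 1 / 3 <= res.tau_iid / 4.0 <= 3
        assert res.converged

    def test_zero_probability_estimate_matches_zero_fraction(self, recovery_fit):
        assert recovery_fit["results"].p0 == pytest.approx(
            float(np.mean(recovery_fit["Y"] == 0)), abs=1e-12
        )


class TestJointFit:
    def test_identical_cell_types_get_identical_fields(self):
        rng = np.random.default_rng(3)
        Y = rng.poisson(3.0, (80, 2))
        results = fit_joint([Y, Y.copy()], family="hurdle")
        np.testing.assert_allclose(results[0].pd, results[1].pd, atol=1e-6)
        np.testing.assert_allclose(results[0].pi, results[1].pi, atol=1e-6)
        assert results[0].tau_rw == results[1].tau_rw

    def test_fixed_hyperparameters_reproduce_single_fit(self):
        rng = np.random.default_rng(4)
        Y = rng.poisson(2.0, (60, 2))
        joint = fit_joint([Y], fix={"tau_rw": 3.0, "tau_iid": 5.0, "k": 2.0})[0]
        single = DecompositionModel(Y, family="hurdle").fit(tau_rw=3.0, tau_iid=5.0, k=2.0)
        np.testing.assert_allclose(joint.pd, single.pd, atol=1e-8)
        np.testing.assert_allclose(joint.pi, single.pi, atol=1e-8)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            fit_joint([np.ones((10, 2)), np.ones((12, 2))], fix={"tau_rw": 1, "tau_iid": 1, "k": 1})


class TestGridSelection:
    def test_49_candidates_and_reference_recovery(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(0, 1, (60, 2)) + sample_rw1(60, 0.5, rng)[:, None]
        model = DecompositionModel(Y, family="gaussian")
        ref = model.fit(tau_rw=1.0 * np.e, tau_iid=2.0, compute_sd=False).pd
        mask = np.ones(60, dtype=bool)
        t_rw, t_iid, table = grid_select_hyperparameters(
            Y, ref, mask, base_tau_rw=1.0, base_tau_iid=2.0, family="gaussian"
        )
        assert len(table) == 49
        # the candidate that generated the reference wins with correlation ~1
        assert t_rw == pytest.approx(np.e, rel=1e-9)
        assert table["pearson_r"].max() == pytest.approx(1.0, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            grid_select_hyperparameters(
                np.ones((10, 2)), np.zeros(10), np.zeros(10, dtype=bool), 1.0, 1.0
            )


class TestComponentFraction:
    def test_arithmetic_and_filters(self):
        res = _fake_results([1.2, 0.5, 2.0], [0.8, -0.1, 2.0])
        counts = np.array([[60.0, 60.0], [60.0, 60.0], [50.0, 50.0]])
        frac = component_fraction(res, counts)
        # bin 1 removed (negative PI), bin 2 removed (mean exactly 50)
        assert list(frac.index) == [0]
        assert frac.iloc[0] == pytest.approx(0.6)

    def test_empty_selection_gives_empty_output(self):
        res = _fake_results([1.0], [1.0])
        frac = component_fraction(res, np.array([[1.0]]))
        assert len(frac) == 0


class TestDifferential:
    def test_identical_posteriors_give_no_calls(self):
        res = _fake_results([0.5, 1.0], [0.0, 0.0])
        tab = differential_components(res, res, [True, True])
        np.testing.assert_array_equal(tab["z"], 0.0)
        np.testing.assert_array_equal(tab["p"], 1.0)
        assert not tab["significant"].any()

    def test_z_to_p_gaussian_quantile(self):
        a = _fake_results([1.959964 * np.sqrt(0.02)], [0.0])
        b = _fake_results([0.0], [0.0])
        tab = differential_components(a, b, [True])
        assert tab["p"].iloc[0] == pytest.approx(0.05, abs=1e-6)

    def test_bh_within_mask_only(self):
        rng = np.random.default_rng(6)
        n = 40
        a = _fake_results(rng.normal(0, 1, n), np.zeros(n))
        b = _fake_results(np.zeros(n), np.zeros(n))
        mask = np.zeros(n, dtype=bool)
        mask[:10] = True
        tab = differential_components(a, b, mask)
        assert tab["q"][~mask].isna().all()
        np.testing.assert_allclose(
            tab["q"][mask].to_numpy(), bh_adjust(tab["p"][mask].to_numpy())
        )

    def test_zero_sd_with_nonzero_delta_flags_infinite_z(self):
        a = _fake_results([1.0], [0.0], pd_sd=[0.0])
        b = _fake_results([0.0], [0.0], pd_sd=[0.0])
        # alpha_sd/pi defaults keep the difference SD 0 for the pd component
        tab = differential_components(a, b, [True])
        assert np.isinf(tab["z"].iloc[0])


class TestBenjaminiHochberg:
    def test_hand_worked_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_matches_brute_force_enumeration(self):
        """q_i = min over j with p_(j) >= p_(i) of m*p_(j)/j, capped at 1."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.random(m)
            expected = np.empty(m)
            order = np.argsort(p)
            ranked = p[order]
            for i in range(m):
                expected[order[i]] = min(
                    min(m * ranked[j] / (j + 1) for j in range(i, m)), 1.0
                )
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


class TestResultsSurface:
    def test_summary_and_frame(self, recovery_fit):
        res = recovery_fit["results"]
        text = res.summary()
        assert "tau_rw" in text and "estimated" in text
        df = res.to_frame()
        assert list(df.columns) == ["alpha", "pd_mean", "pd_sd", "pi_mean", "pi_sd"]
        assert len(df) == res.n_bins

    def test_all_zero_chromosome_rejected(self):
        with pytest.raises(ValueError):
            DecompositionModel(np.zeros((10, 2)), family="hurdle")
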