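"""Kalman recursion, l1 projection and smoother contracts.

The classical-filter oracle here is an independent textbook
implementation (explicit-inverse Kalman equations) kept deliberately
separate from the package's solver-based update.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lassokalman import (
    GeneTrackState,
    TrackOptions,
    extract_gene_problem,
    filter_gene,
    lasso_project,
    predict,
    smooth_gene,
    track_network,
    update,
)
from lassokalman.tracker import universal_threshold
from .conftest import make_observations


def textbook_kalman(problems, q, r, p0, a0):
    """Reference unconstrained filter with explicit inverses."""
    p = problems[0][0].shape[1]
    a = np.asarray(a0, dtype=float).copy()
    P = p0 * np.eye(p)
    out = []
    for H, y in problems:
        P = P + q * np.eye(p)
        S = H @ P @ H.T + r * np.eye(H.shape[0])
        K = P @ H.T @ np.linalg.inv(S)
        a = a + K @ (y - H @ a)
        P = (np.eye(p) - K @ H) @ P
        out.append((a.copy(), P.copy()))
    return out


def make_state(p=3, a=None, P=None, q=0.0, r=1.0):
    return GeneTrackState(
        gene_index=0,
        a=np.zeros(p) if a is None else np.asarray(a, float),
        P=np.eye(p) if P is None else np.asarray(P, float),
        Q=q * np.eye(p),
        r_scale=r,
    )


class TestPredict:
    def test_zero_process_noise_is_identity(self, rng):
        st_ = make_state(a=rng.standard_normal(3))
        out = predict(st_)
        np.testing.assert_array_equal(out.a, st_.a)
        np.testing.assert_array_equal(out.P, st_.P)

    def test_covariance_is_additive(self):
        out = predict(make_state(q=0.1))
        np.testing.assert_allclose(out.P, 1.1 * np.eye(3))

    def test_repeated_prediction_accumulates(self):
        st_ = make_state(q=0.25)
        for _ in range(4):
            st_ = predict(st_)
        np.testing.assert_allclose(st_.P, (1 + 4 * 0.25) * np.eye(3))


class TestUpdate:
    def test_scalar_hand_case(self):
        # p = m = 1, P = 1, H = 1, R = 1, a = 0, y = 2 -> a = 1, P = 0.5
        st_ = make_state(p=1, r=1.0)
        out = update(st_, np.array([[1.0]]), np.array([2.0]))
        np.testing.assert_allclose(out.a, [1.0])
        np.testing.assert_allclose(out.P, [[0.5]])

    def test_full_observation_trusted_in_low_noise_limit(self, rng):
        y = rng.standard_normal(4)
        st_ = make_state(p=4, r=1e-12)
        out = update(st_, np.eye(4), y)
        np.testing.assert_allclose(out.a, y, atol=1e-9)

    def test_zero_covariance_gives_zero_gain(self, rng):
        a = rng.standard_normal(3)
        st_ = make_state(a=a, P=np.zeros((3, 3)))
        out = update(st_, rng.standard_normal((2, 3)), rng.standard_normal(2))
        np.testing.assert_array_equal(out.a, a)

    def test_covariance_stays_symmetric_psd(self, rng):
        st_ = make_state(p=5, q=0.01, r=0.1)
        for _ in range(10):
            st_ = predict(st_)
            st_ = update(
                st_, rng.standard_normal((3, 5)), rng.standard_normal(3)
            )
            np.testing.assert_allclose(st_.P, st_.P.T, atol=1e-10)
            assert np.linalg.eigvalsh(st_.P).min() > -1e-8


class TestLassoProject:
    def test_lambda_zero_is_identity(self, rng):
        a = rng.standard_normal(6)
        np.testing.assert_array_equal(lasso_project(a, None, 0.0), a)

    def test_large_lambda_gives_exact_zero(self, rng):
        a = rng.standard_normal(6)
        lam = 2 * np.abs(a).max() + 1.0
        assert np.all(lasso_project(a, None, lam) == 0.0)

    def test_hand_computed_soft_threshold(self):
        out = lasso_project(np.array([1.0, -0.2, 0.05]), None, 0.5)
        np.testing.assert_allclose(out, [0.75, 0.0, 0.0])

    def test_agrees_with_brute_force_prox(self, rng):
        # independent oracle: scalar minimization of the separable objective
        from scipy.optimize import minimize_scalar

        for _ in range(10):
            a = rng.standard_normal(5) * rng.uniform(0.1, 3)
            lam = rng.uniform(0, 2)
            ours = lasso_project(a, None, lam)
            for j in range(5):
                ref = minimize_scalar(
                    lambda z: (a[j] - z) ** 2 + lam * abs(z),
                    bounds=(-20, 20),
                    method="bounded",
                    options={"xatol": 1e-12},
                ).x
                assert abs(ours[j] - ref) < 5e-8

    def test_iterative_solver_matches_closed_form(self, rng):
        a = rng.standard_normal(8)
        lam = 0.7
        np.testing.assert_allclose(
            lasso_project(a, None, lam, method="iterative"),
            lasso_project(a, None, lam),
            atol=1e-9,
        )

    @given(
        st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=1, max_size=8
        ),
        st.floats(0, 5),
        st.floats(0, 5),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_nonzero_count_monotone_in_lambda(self, vals, lam1, lam2):
        a = np.asarray(vals)
        lo, hi = sorted([lam1, lam2])
        n_lo = np.count_nonzero(lasso_project(a, None, lo))
        n_hi = np.count_nonzero(lasso_project(a, None, hi))
        assert n_hi <= n_lo


class TestFilterGene:
    def test_lambda0_plain_matches_textbook_oracle(self, rng):
        for p, n in [(3, 4), (8, 6), (5, 2)]:
            _, obs = make_observations(rng, p=p, n_epochs=n, m=3, noise_sd=0.2)
            problems = extract_gene_problem(obs, 0)
            opts = TrackOptions(
                lambda_=0.0, q_scale=0.05, r_scale=0.2, p0_scale=2.0,
                readout="plain",
            )
            a0 = rng.standard_normal(p)
            traj = filter_gene(problems, opts, a0=a0)
            ref = textbook_kalman(problems, 0.05, 0.2, 2.0, a0)
            for (a_ref, P_ref), a_est, P_est in zip(
                ref, traj.filtered, traj.filtered_cov
            ):
                np.testing.assert_allclose(a_est, a_ref, atol=1e-10)
                np.testing.assert_allclose(P_est, P_ref, atol=1e-10)

    def test_consistent_start_noiseless_single_epoch(self, rng):
        A, obs = make_observations(rng, p=4, n_epochs=1, m=6, noise_sd=0.0)
        problems = extract_gene_problem(obs, 2)
        opts = TrackOptions(lambda_=0.0, r_scale=1e-9, readout="plain")
        traj = filter_gene(problems, opts, a0=A[2])
        np.testing.assert_allclose(traj.filtered[0], A[2], atol=1e-8)

    def test_exact_recovery_noiseless_overdetermined(self, rng):
        # m_k >= p, zero noise, lambda = 0: final estimate recovers truth
        A, obs = make_observations(rng, p=5, n_epochs=3, m=6, noise_sd=0.0)
        opts = TrackOptions(lambda_=0.0, r_scale=1e-9, q_scale=0.0,
                            readout="plain")
        for i in range(5):
            traj = filter_gene(extract_gene_problem(obs, i), opts)
            np.testing.assert_allclose(traj.filtered[-1], A[i], atol=1e-6)

    def test_sparse_support_recovered(self, rng):
        # 2 nonzero incoming edges in p=10, 7 observations x 5 epochs
        p = 10
        a_true = np.zeros(p)
        a_true[[2, 7]] = [1.2, -0.8]
        problems = []
        for _ in range(5):
            X = rng.standard_normal((7, p))
            problems.append((X, X @ a_true + 0.05 * rng.standard_normal(7)))
        opts = TrackOptions(
            lambda_=0.3, q_scale=1e-3, r_scale=0.05**2, readout="plain"
        )
        traj = filter_gene(problems, opts)
        support = np.flatnonzero(traj.filtered[-1])
        assert set(support) == {2, 7}


class TestSmoothGene:
    def _problems(self, rng, p=6, n=5, m=4, noise=0.1):
        _, obs = make_observations(rng, p=p, n_epochs=n, m=m, noise_sd=noise)
        return extract_gene_problem(obs, 0)

    def test_single_epoch_smoothed_close_to_filtered(self, rng):
        problems = self._problems(rng, n=1)
        opts = TrackOptions(lambda_=0.0, p0_backward_scale=1e6,
                            readout="plain")
        traj = smooth_gene(problems, opts)
        np.testing.assert_allclose(
            traj.smoothed[0], traj.filtered[0], rtol=1e-4, atol=1e-6
        )

    def test_static_truth_gives_nearly_constant_smoothed_track(self, rng):
        A, obs = make_observations(rng, p=4, n_epochs=4, m=5, noise_sd=0.0)
        opts = TrackOptions(lambda_=0.0, q_scale=0.0, r_scale=1e-6,
                            readout="plain")
        traj = smooth_gene(extract_gene_problem(obs, 1), opts)
        for a_k in traj.smoothed:
            np.testing.assert_allclose(a_k, traj.smoothed[0], atol=1e-5)

    def test_smoothing_reduces_posterior_variance(self, rng):
        problems = self._problems(rng, p=8, n=5, m=5)
        opts = TrackOptions(lambda_=0.1, q_scale=0.05, r_scale=0.01)
        traj = smooth_gene(problems, opts)
        for Pf, Ps in zip(traj.filtered_cov, traj.smoothed_cov):
            assert np.all(np.diag(Ps) <= np.diag(Pf) + 1e-8)
        mean_f = np.mean([np.diag(P).mean() for P in traj.filtered_cov])
        mean_s = np.mean([np.diag(P).mean() for P in traj.smoothed_cov])
        assert mean_s < mean_f

    def test_universal_threshold_formula(self):
        P = np.diag([0.04, 0.09, 1.0, 0.0])
        thr = universal_threshold(P)
        c = np.sqrt(2 * np.log(4))
        np.testing.assert_allclose(thr, c * np.array([0.2, 0.3, 1.0, 0.0]))


class TestTrackNetwork:
    def test_matches_independent_per_gene_runs(self, rng, bench_instance):
        cfg, networks, obs = bench_instance
        opts = cfg.matched_track_options()
        traj = track_network(obs, opts, lambdas=0.05)
        gene_opts = TrackOptions(**{**opts.__dict__, "lambda_": 0.05})
        ref = smooth_gene(extract_gene_problem(obs, 3), gene_opts, gene_index=3)
        for k in range(obs.n_epochs):
            np.testing.assert_array_equal(traj.matrices[k][3], ref.smoothed[k])

    def test_deterministic_across_worker_counts(self, bench_instance):
        cfg, _, obs = bench_instance
        opts = cfg.matched_track_options()
        t1 = track_network(obs, opts, lambdas=0.1, n_jobs=1)
        t4 = track_network(obs, opts, lambdas=0.1, n_jobs=4)
        for A1, A4 in zip(t1.matrices, t4.matrices):
            np.testing.assert_array_equal(A1, A4)

    def test_lasso_variant_sparser_than_classical_every_epoch(
        self, bench_instance
    ):
        cfg, _, obs = bench_instance
        opts = cfg.matched_track_options()
        sparse = track_network(obs, opts, lambdas=0.1)
        classical = track_network(
            obs,
            TrackOptions(**{**opts.__dict__, "readout": "plain"}),
            lambdas=0.0,
            smooth=False,
        )
        for As, Ac in zip(sparse.matrices, classical.matrices):
            assert np.count_nonzero(As) < np.count_nonzero(Ac)
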