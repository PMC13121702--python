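import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from africo.reservoir import (
    ESNModel,
    ReservoirInitSpec,
    closed_loop_matrix,
    delay_embed,
    esn_simulate,
    esn_step,
    linear_frf,
    make_reservoir,
    model_from_json,
    model_to_json,
    random_weight_matrix,
    set_spectral_radius,
    spectral_radius,
)


class TestRandomWeightMatrix:
    def test_entries_within_range_and_reproducible(self):
        A = random_weight_matrix(2, 2, (-1, 1), seed=5)
        B = random_weight_matrix(2, 2, (-1, 1), seed=5)
        assert A.shape == (2, 2)
        assert np.all(A >= -1) and np.all(A <= 1)
        np.testing.assert_array_equal(A, B)

    def test_large_sample_mean_near_zero(self):
        # mean of 1e6 uniform(-1,1) draws: std of the mean = 1/sqrt(3e6) ~ 6e-4
        A = random_weight_matrix(1000, 1000, (-1, 1), seed=0)
        assert abs(A.mean()) < 0.01

    def test_rejects_bad_dimensions(self):
        with pytest.raises(ValueError):
            random_weight_matrix(0, 3)


class TestSpectralRadius:
    def test_identity_scaling(self):
        W = set_spectral_radius(np.eye(3), 0.9)
        np.testing.assert_allclose(W, 0.9 * np.eye(3))

    def test_nilpotent_rejected(self):
        W = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            set_spectral_radius(W, 0.9)

    def test_matches_eigenvalue_oracle(self, rng):
        W = set_spectral_radius(rng.uniform(-1, 1, (20, 20)), 0.85)
        rho = np.max(np.abs(np.linalg.eigvals(W)))
        assert abs(rho - 0.85) < 1e-9

    def test_idempotent_at_target(self, rng):
        W = set_spectral_radius(rng.uniform(-1, 1, (10, 10)), 0.7)
        W2 = set_spectral_radius(W, 0.7)
        np.testing.assert_allclose(W, W2, rtol=1e-12)


class TestMakeReservoir:
    @pytest.mark.parametrize("eigenspectrum", ["unconstrained", "uniform"])
    def test_radius_in_requested_range(self, eigenspectrum):
        spec = ReservoirInitSpec(
            N=40, spectral_radius_range=(0.8, 0.9), eigenspectrum=eigenspectrum, seed=2
        )
        W = make_reservoir(spec)
        assert W.shape == (40, 40)
        assert 0.8 <= spectral_radius(W) <= 0.9
        # real matrix: complex eigenvalues occur in conjugate pairs
        assert np.isrealobj(W)

    def test_scalar_reservoir(self):
        W = make_reservoir(ReservoirInitSpec(N=1, seed=0))
        assert W.shape == (1, 1)
        assert 0.8 <= abs(W[0, 0]) <= 0.9

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            ReservoirInitSpec(N=5, spectral_radius_range=(0.5, 1.2))


class TestEsnStep:
    def test_identity_passthrough(self):
        model = ESNModel(
            W=np.zeros((2, 2)),
            W_in=np.eye(2),
            W_fb=np.zeros((2, 2)),
            activation="identity",
            feedback_mode="state",
        )
        v = np.array([0.3, -0.7])
        np.testing.assert_allclose(esn_step(model, np.array([5.0, -2.0]), v), v)

    def test_tanh_bounded(self, small_state_model, rng):
        x = rng.uniform(-1, 1, 5)
        out = esn_step(small_state_model, x, np.array([3.0]))
        assert np.all(np.abs(out) < 1.0)

    def test_matches_affine_oracle(self, small_linear_model, rng):
        m = small_linear_model
        x = rng.standard_normal(5)
        u = rng.standard_normal(1)
        expected = (m.W + m.W_in @ m.W_fb) @ x + (m.W_in @ u)
        np.testing.assert_allclose(esn_step(m, x, u), expected, rtol=1e-12)

    def test_shape_mismatch_rejected(self, small_state_model):
        with pytest.raises(ValueError):
            esn_step(small_state_model, np.zeros(4), np.zeros(1))


class TestEsnSimulate:
    def test_zero_input_zero_trajectory(self, small_state_model):
        traj = esn_simulate(small_state_model, np.zeros(10))
        np.testing.assert_array_equal(traj.X, 0.0)

    def test_lengths_match(self, small_state_model):
        traj = esn_simulate(small_state_model, np.ones(17))
        assert len(traj.X) == len(traj.U) == 17

    def test_impulse_matches_matrix_power_oracle(self, small_linear_model):
        m = small_linear_model
        U = np.zeros(8)
        U[0] = 1.0
        traj = esn_simulate(m, U)
        A_cl = closed_loop_matrix(m)
        b = m.W_in[:, 0]
        np.testing.assert_array_equal(traj.X[0], 0.0)
        for k in range(1, 8):
            np.testing.assert_allclose(
                traj.X[k], np.linalg.matrix_power(A_cl, k - 1) @ b, atol=1e-12
            )

    def test_superposition_for_identity_activation(self, small_linear_model, rng):
        u1 = rng.standard_normal(30)
        u2 = rng.standard_normal(30)
        a, b = 0.7, -1.3
        X_sum = esn_simulate(small_linear_model, a * u1 + b * u2).X
        X_parts = (
            a * esn_simulate(small_linear_model, u1).X
            + b * esn_simulate(small_linear_model, u2).X
        )
        np.testing.assert_allclose(X_sum, X_parts, atol=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_tanh_states_bounded_for_any_bounded_input(self, scale):
        rng = np.random.default_rng(0)
        W = set_spectral_radius(rng.uniform(-1, 1, (6, 6)), 0.85)
        model = ESNModel(
            W=W,
            W_in=rng.uniform(-1, 1, (6, 1)),
            W_fb=rng.uniform(-1, 1, (1, 6)),
            activation="tanh",
            feedback_mode="state",
        )
        traj = esn_simulate(model, scale * np.sin(np.arange(50)))
        assert np.all(np.abs(traj.X) <= 1.0)


class TestDelayEmbed:
    def test_zero_lag_identity(self):
        u = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(delay_embed(u, 0), u[:, None])

    def test_zero_padded_history(self):
        out = delay_embed(np.array([1.0, 2.0, 3.0]), 1)
        np.testing.assert_array_equal(out, [[1, 0], [2, 1], [3, 2]])

    def test_output_dimension(self):
        assert delay_embed(np.arange(10.0), 7).shape == (10, 8)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            delay_embed(np.arange(3.0), -1)


class TestClosedLoop:
    def test_zero_feedback_returns_reservoir(self, small_linear_model):
        m = small_linear_model
        m.W_fb = np.zeros_like(m.W_fb)
        np.testing.assert_array_equal(closed_loop_matrix(m), m.W)

    def test_scalar_arithmetic(self):
        m = ESNModel(
            W=np.array([[0.5]]),
            W_in=np.array([[2.0]]),
            W_fb=np.array([[0.1]]),
            activation="identity",
            feedback_mode="state",
        )
        np.testing.assert_allclose(closed_loop_matrix(m), [[0.7]])

    def test_matches_numerical_jacobian(self, small_linear_model, rng):
        m = small_linear_model
        x = rng.standard_normal(5)
        u = np.zeros(1)
        eps = 1e-7
        J = np.empty((5, 5))
        for i in range(5):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            J[:, i] = (esn_step(m, xp, u) - esn_step(m, xm, u)) / (2 * eps)
        np.testing.assert_allclose(J, closed_loop_matrix(m), atol=1e-6)

    def test_wrong_mode_rejected(self):
        m = ESNModel(
            W=np.array([[0.5]]),
            W_in=np.array([[1.0]]),
            W_fb=np.array([[0.1]]),
            feedback_mode="output",
        )
        with pytest.raises(ValueError):
            closed_loop_matrix(m)


class TestLinearFrf:
    def test_pure_delay(self):
        H = linear_frf(np.zeros((1, 1)), [[1.0]], [[1.0]], np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(H, np.exp(-1j * np.array([0.0, 0.5, 1.0])))

    def test_dc_gain(self):
        H = linear_frf(np.array([[0.5]]), [[1.0]], [[1.0]], np.array([0.0]))
        np.testing.assert_allclose(H[0], 2.0)

    def test_unstable_rejected(self):
        with pytest.raises(ValueError):
            linear_frf(np.array([[1.1]]), [[1.0]], [[1.0]], np.array([0.0]))

    def test_matches_empirical_transfer_estimate(self, rng):
        # white-noise simulation of a linear state-feedback ESN vs the
        # analytic resolvent formula, via Welch cross/auto spectra
        from scipy import signal

        W = set_spectral_radius(rng.uniform(-1, 1, (8, 8)), 0.6)
        model = ESNModel(
            W=W,
            W_in=rng.uniform(-1, 1, (8, 1)),
            W_fb=0.05 * rng.uniform(-1, 1, (1, 8)),
            activation="identity",
            feedback_mode="state",
            readout=rng.uniform(-1, 1, (1, 8)),
        )
        U = rng.standard_normal(200_000)
        traj = esn_simulate(model, U)
        # predicted output lags the input by one step through the state
        f, Puy = signal.csd(U, traj.Y, nperseg=4096)
        _, Puu = signal.welch(U, nperseg=4096)
        H_emp = Puy / Puu
        omegas = 2 * np.pi * f
        H_ana = linear_frf(
            closed_loop_matrix(model), model.W_in, np.asarray(model.readout), omegas
        )
        keep = (omegas > 0.1) & (omegas < 3.0)
        err = np.abs(np.abs(H_emp[keep]) - np.abs(H_ana[keep])) / np.abs(H_ana[keep])
        assert np.max(err) < 0.02


class TestSerialization:
    def test_roundtrip_linear_readout(self, small_state_model):
        small_state_model.readout = np.arange(5.0).reshape(1, 5)
        doc = model_to_json(small_state_model)
        back = model_from_json(doc)
        np.testing.assert_array_equal(back.W, small_state_model.W)
        np.testing.assert_array_equal(
            np.asarray(back.readout).ravel(), np.arange(5.0)
        )
        traj_a = esn_simulate(small_state_model, np.sin(np.arange(20)))
        traj_b = esn_simulate(back, np.sin(np.arange(20)))
        np.testing.assert_allclose(traj_a.Y, traj_b.Y)
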