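"""Free-energy estimators: TI, Gauss-quadrature TI, BAR, MBAR."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp

from alchest.estimators import (
    BAR,
    MBAR,
    TI,
    EstimatorConfig,
    GaussianQuadratureTI,
    bar_fit,
    gauss_legendre_points,
    mbar_fit,
    ti_fit,
)
from alchest.exceptions import EstimationError, ValidationError
from alchest.testsystems import HarmonicSpec, sample

from conftest import harmonic_unk, make_dhdl, make_unk


def mbar_oracle(u, n_k):
    """Independent MBAR solution: scipy BFGS on the convex objective.

    The package solves the self-consistent equations by fixed-point +
    Newton iteration; this oracle instead minimizes
    Σ_n ln Σ_k N_k exp(f_k − u_nk) − Σ_k N_k f_k numerically, a wholly
    different route to the same stationary point.
    """
    n_k = np.asarray(n_k, dtype=float)

    def objective(f_free):
        f = np.concatenate([[0.0], f_free])
        return float(
            np.sum(logsumexp(np.log(n_k)[None, :] + f[None, :] - u, axis=1))
            - np.dot(n_k, f)
        )

    res = minimize(objective, np.zeros(u.shape[1] - 1), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 1000})
    return np.concatenate([[0.0], res.x])


class TestTI:
    def test_constant_gradient(self, small_dhdl):
        result = ti_fit(small_dhdl)
        assert result.endpoint()[0] == pytest.approx(1.0, abs=1e-12)

    def test_trapezoid_arithmetic(self):
        # window means 0, 1, 2 at lambda 0, 0.5, 1 integrate to 1.0
        table = make_dhdl(
            [[-0.5, 0.5], [0.5, 1.5], [1.5, 2.5]], [0.0, 0.5, 1.0]
        )
        result = ti_fit(table)
        assert result.delta_f[0, 2] == pytest.approx(1.0, abs=1e-12)
        # intermediate entry is the partial integral
        assert result.delta_f[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_antisymmetry_and_path_additivity(self, rng):
        table = make_dhdl(
            [rng.normal(size=50) for _ in range(4)],
            [0.0, 0.3, 0.7, 1.0],
        )
        df = ti_fit(table).delta_f
        np.testing.assert_allclose(df, -df.T, atol=1e-12)
        assert df[0, 2] == pytest.approx(df[0, 1] + df[1, 2], abs=1e-12)

    def test_variance_propagation(self, rng):
        # two windows: var(Δf) = (Δλ/2)^2 (sem0^2 + sem1^2)
        a, b = rng.normal(size=100), rng.normal(size=100)
        table = make_dhdl([a, b], [0.0, 1.0])
        result = ti_fit(table)
        expected = 0.25 * (np.var(a, ddof=1) / 100 + np.var(b, ddof=1) / 100)
        assert result.d_delta_f[0, 1] == pytest.approx(math.sqrt(expected),
                                                       rel=1e-12)

    def test_single_sample_window_rejected(self):
        table = make_dhdl([[1.0], [1.0, 2.0]], [0.0, 1.0])
        with pytest.raises(EstimationError, match="at least 2"):
            ti_fit(table)

    def test_multi_component_path_single_change_per_segment(self, rng):
        # (0,0) -> (0,1) -> (1,1): valid staged path
        table = make_dhdl(
            [rng.normal(1.0, 0.1, (30, 2)) for _ in range(3)],
            [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)],
            names=("vdw-lambda", "coul-lambda"),
        )
        result = ti_fit(table)
        assert result.n_states == 3

    def test_diagonal_path_rejected(self, rng):
        table = make_dhdl(
            [rng.normal(size=(30, 2)) for _ in range(2)],
            [(0.0, 0.0), (1.0, 1.0)],
            names=("vdw-lambda", "coul-lambda"),
        )
        with pytest.raises(EstimationError, match="exactly one"):
            ti_fit(table)

    def test_harmonic_recovery(self):
        spec = HarmonicSpec(seed=11, phi=0.0, n_samples=5000)
        dhdl, _ = sample(spec)
        value, error = ti_fit(dhdl).endpoint()
        assert abs(value - spec.analytic_delta_f) < 3 * error


class TestGaussianQuadratureTI:
    def test_single_point_rule_has_unit_weight(self):
        table = make_dhdl([[2.0, 4.0]], [0.5])  # mean 3.0 at the 1-pt node
        result = GaussianQuadratureTI(n_points=1).fit(table).result_
        assert result.endpoint()[0] == pytest.approx(3.0, abs=1e-12)

    def test_three_point_rule_integrates_quartic_exactly(self):
        # noiseless g(λ)=λ⁴ at the 3 nodes; ∫₀¹ λ⁴ dλ = 1/5
        nodes, _ = gauss_legendre_points(3)
        table = make_dhdl(
            [[x**4, x**4] for x in nodes], list(nodes)
        )
        value, error = GaussianQuadratureTI(n_points=3).fit(table).result_.endpoint()
        assert value == pytest.approx(0.2, abs=1e-12)
        assert error == 0.0

    def test_shifted_nodes_rejected(self):
        nodes, _ = gauss_legendre_points(3)
        table = make_dhdl(
            [[1.0, 1.0]] * 3, [min(1.0, x + 0.01) for x in nodes]
        )
        with pytest.raises(ValidationError, match="Gauss-Legendre"):
            GaussianQuadratureTI(n_points=3).fit(table)

    def test_too_many_points_rejected(self):
        with pytest.raises(ValueError):
            gauss_legendre_points(17)

    def test_harmonic_recovery_on_nodes(self):
        spec = HarmonicSpec.gauss_legendre(8, seed=12, phi=0.0,
                                           n_samples=5000)
        dhdl, _ = sample(spec)
        value, error = GaussianQuadratureTI().fit(dhdl).result_.endpoint()
        assert abs(value - spec.analytic_delta_f) < 3 * error


class TestBAR:
    def test_symmetric_null(self):
        # forward and reverse works identically zero -> Δf = 0
        u = np.zeros((40, 2))
        table = make_unk(u, [0] * 20 + [1] * 20, [0.0, 1.0])
        result = bar_fit(table)
        assert result.delta_f[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_recovery(self, two_state_unk):
        value, error = bar_fit(two_state_unk).endpoint()
        assert abs(value - 0.5 * math.log(4)) < 3 * error

    def test_two_state_equivalence_with_mbar(self, two_state_unk):
        bar_df = bar_fit(two_state_unk).delta_f[0, 1]
        mbar_df = mbar_fit(two_state_unk)[0].delta_f[0, 1]
        assert abs(bar_df - mbar_df) < 1e-6

    def test_unsampled_state_rejected(self, rng):
        u = rng.normal(size=(40, 3))
        table = make_unk(u, [0] * 20 + [2] * 20, [0.0, 0.5, 1.0])
        with pytest.raises(EstimationError, match="no samples"):
            bar_fit(table)

    def test_path_sum_for_non_adjacent_states(self, rng):
        table = harmonic_unk(rng, [1.0, 2.0, 4.0], 1500)
        result = bar_fit(table)
        assert result.delta_f[0, 2] == pytest.approx(
            result.delta_f[0, 1] + result.delta_f[1, 2], abs=1e-12
        )
        assert result.d_delta_f[0, 2] == pytest.approx(
            math.hypot(result.d_delta_f[0, 1], result.d_delta_f[1, 2]),
            rel=1e-12,
        )


class TestMBAR:
    def test_indistinguishable_states(self, rng):
        # identical columns per row -> all Δf zero, uniform weights
        base = rng.normal(size=60)
        u = np.tile(base[:, None], (1, 3))
        table = make_unk(u, [0] * 20 + [1] * 20 + [2] * 20, [0.0, 0.5, 1.0])
        result, weights = mbar_fit(table)
        np.testing.assert_allclose(result.delta_f, 0.0, atol=1e-10)
        np.testing.assert_allclose(weights.W, 1.0 / 60, rtol=1e-10)

    def test_harmonic_multistate_recovery(self, rng):
        table = harmonic_unk(rng, [1.0, 2.0, 4.0], 5000)
        result, _ = mbar_fit(table)
        assert abs(result.delta_f[0, 2] - 0.5 * math.log(4)) \
            < 3 * result.d_delta_f[0, 2]
        assert abs(result.delta_f[0, 1] - 0.5 * math.log(2)) \
            < 3 * result.d_delta_f[0, 1]

    def test_path_additivity_exact(self, rng):
        table = harmonic_unk(rng, [1.0, 1.5, 3.0], 300)
        result, _ = mbar_fit(table)
        df = result.delta_f
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert df[i, j] + df[j, k] == pytest.approx(
                        df[i, k], abs=1e-10
                    )

    def test_additive_row_constant_invariance(self, rng):
        table = harmonic_unk(rng, [1.0, 4.0], 500, states=[0.0, 1.0])
        shifted_data = table.data + rng.normal(size=(len(table), 1))
        shifted = type(table)(shifted_data, table.metadata)
        a, _ = mbar_fit(table)
        b, _ = mbar_fit(shifted)
        np.testing.assert_allclose(a.delta_f, b.delta_f, atol=1e-8)

    def test_matches_independent_convex_oracle(self):
        """Five random K=3, N=100 instances against scipy minimization."""
        rng = np.random.default_rng(2024)
        for _ in range(5):
            ks = rng.uniform(0.5, 4.0, 3)
            table = harmonic_unk(rng, ks, 100)
            est = MBAR().fit(table)
            u = table.data.to_numpy()
            f_ref = mbar_oracle(u, [100, 100, 100])
            np.testing.assert_allclose(
                est.free_energies_, f_ref - f_ref[0], atol=1e-6
            )

    def test_unsampled_state_gets_perturbation_estimate(self, rng):
        # state 1 unsampled: MBAR still reports its free energy
        ks = [1.0, 2.0, 4.0]
        xs = [rng.normal(0, 1 / math.sqrt(k), 400) for k in (1.0, 4.0)]
        x = np.concatenate(xs)
        u = 0.5 * np.outer(x**2, ks)
        table = make_unk(u, [0] * 400 + [2] * 400, [0.0, 0.5, 1.0])
        result, weights = mbar_fit(table)
        assert abs(result.delta_f[0, 1] - 0.5 * math.log(2)) < 0.1
        col = weights.W.sum(axis=0)
        np.testing.assert_allclose(col, 1.0, atol=1e-8)

    def test_weight_identities(self, rng):
        table = harmonic_unk(rng, [1.0, 2.0, 4.0], 400)
        _, weights = mbar_fit(table)
        np.testing.assert_allclose(weights.W.sum(axis=0), 1.0, atol=1e-8)
        n_k = np.asarray(weights.N_k.N_k, dtype=float)
        np.testing.assert_allclose(weights.W @ n_k, 1.0, atol=1e-8)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EstimatorConfig(relative_tolerance=2.0)
        with pytest.raises(ValueError):
            EstimatorConfig(maximum_iterations=0)

    def test_nonconvergence_raises(self, rng):
        from alchest.exceptions import ConvergenceError

        table = harmonic_unk(rng, [1.0, 16.0], 200, states=[0.0, 1.0])
        with pytest.raises(ConvergenceError):
            MBAR(maximum_iterations=2).fit(table)


def test_sklearn_contract():
    """Estimators expose get_params/set_params and clone cleanly."""
    from sklearn.base import clone

    est = MBAR(maximum_iterations=500, relative_tolerance=1e-8)
    params = est.get_params()
    assert params["maximum_iterations"] == 500
    twin = clone(est)
    assert twin.get_params() == params
    twin.set_params(maximum_iterations=99)
    assert twin.maximum_iterations == 99


def test_estimators_mutually_consistent(rng):
    """TI and MBAR agree within mutual 3σ on the same harmonic draw."""
    spec = HarmonicSpec(seed=77, phi=0.0, n_samples=4000)
    dhdl, unk = sample(spec)
    ti_v, ti_e = ti_fit(dhdl).endpoint()
    mb_v, mb_e = mbar_fit(unk)[0].endpoint()
    ba_v, ba_e = bar_fit(unk).endpoint()
    assert abs(ti_v - mb_v) < 3 * math.hypot(ti_e, mb_e)
    assert abs(ba_v - mb_v) < 3 * math.hypot(ba_e, mb_e)
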