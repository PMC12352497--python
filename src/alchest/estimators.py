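"""Free-energy estimators: TI, TI with Gaussian quadrature, BAR, MBAR.

All estimators follow the scikit-learn contract: parameters are set at
construction, :meth:`fit` consumes one of the standard tables, and the
results are exposed as fitted attributes with a trailing underscore —
``delta_f_`` (K×K matrix of free-energy differences in kT, entry [i, j]
being f_j − f_i), ``d_delta_f_`` (matched standard errors) and
``states_`` (the λ-vectors labelling rows/columns).  The same results
are bundled into a :class:`FreeEnergyResult` under ``result_``.

Two estimator families are implemented:

* **TI** integrates the mean Hamiltonian gradient ⟨∂H/∂λ⟩ over the
  alchemical path, either by the trapezoid rule on the sampled windows
  (:class:`TI`) or by Gauss–Legendre quadrature when the windows sit on
  the quadrature nodes (:class:`GaussianQuadratureTI`).

* **FEP-family** estimators work from reduced-potential differences:
  :class:`BAR` solves Bennett's optimal two-state equation for each
  adjacent pair of sampled states, and :class:`MBAR` solves the
  multistate generalization self-consistently over all states at once,
  also yielding the per-sample weight matrix used by overlap
  diagnostics.  Both are invariant to adding an arbitrary per-row
  constant to the reduced potentials, so inputs may be raw reduced
  potentials or differences relative to the sampling state.

MBAR is solved by self-consistent iteration with a switch to Newton's
method on the sampled-state free energies, using log-sum-exp
stabilization throughout; uncertainties come from the standard
asymptotic covariance of the weight matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .datamodel import (
    EnergyMetadata,
    GradientTable,
    LambdaVector,
    ReducedPotentialTable,
    StateCounts,
    state_counts,
)
from .exceptions import ConvergenceError, EstimationError, ValidationError

__all__ = [
    "FreeEnergyResult",
    "EstimatorConfig",
    "MbarWeights",
    "BaseFreeEnergyEstimator",
    "TI",
    "GaussianQuadratureTI",
    "BAR",
    "MBAR",
    "ti_fit",
    "ti_gauss_fit",
    "bar_fit",
    "mbar_fit",
]

#: Gauss–Legendre rules are supported up to this many points.
MAX_GAUSS_POINTS = 16

#: absolute per-component tolerance for matching windows to quadrature nodes
NODE_MATCH_TOL = 1e-3


@dataclass(frozen=True)
class FreeEnergyResult:
    """K×K free-energy difference matrix with matched uncertainties.

    ``delta_f[i, j] = f_j − f_i`` in kT (antisymmetric, zero diagonal);
    ``d_delta_f`` is the matching symmetric matrix of standard errors.
    """

    states: tuple[LambdaVector, ...]
    delta_f: np.ndarray
    d_delta_f: np.ndarray
    metadata: EnergyMetadata

    def __post_init__(self) -> None:
        k = len(self.states)
        df = np.asarray(self.delta_f, dtype=float)
        dd = np.asarray(self.d_delta_f, dtype=float)
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "delta_f", df)
        object.__setattr__(self, "d_delta_f", dd)
        if df.shape != (k, k) or dd.shape != (k, k):
            raise ValidationError(
                f"matrices must be {k}x{k}, got {df.shape} and {dd.shape}"
            )
        scale = max(1.0, float(np.max(np.abs(df))) if k else 1.0)
        if np.max(np.abs(df + df.T)) > 1e-10 * scale:
            raise ValidationError("delta_f must be antisymmetric")
        if np.max(np.abs(np.diag(df))) > 1e-12:
            raise ValidationError("delta_f diagonal must be zero")
        if np.max(np.abs(dd - dd.T)) > 1e-10 or np.any(dd < 0):
            raise ValidationError("d_delta_f must be symmetric and nonnegative")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def endpoint(self) -> tuple[float, float]:
        """Δf between the first and last state, with its standard error."""
        return float(self.delta_f[0, -1]), float(self.d_delta_f[0, -1])

    def _labels(self) -> list:
        if self.states and self.states[0].n_components == 1:
            return [s.values[0] for s in self.states]
        return [s.values for s in self.states]

    def delta_f_frame(self) -> pd.DataFrame:
        labels = self._labels()
        return pd.DataFrame(self.delta_f, index=labels, columns=labels)

    def d_delta_f_frame(self) -> pd.DataFrame:
        labels = self._labels()
        return pd.DataFrame(self.d_delta_f, index=labels, columns=labels)


@dataclass(frozen=True)
class EstimatorConfig:
    """Solver knobs shared by the iterative estimators."""

    maximum_iterations: int = 10000
    relative_tolerance: float = 1e-10
    initial_free_energies: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.maximum_iterations < 1:
            raise ValueError("maximum_iterations must be positive")
        if not 0 < self.relative_tolerance < 1:
            raise ValueError("relative_tolerance must be in (0, 1)")


@dataclass(frozen=True)
class MbarWeights:
    """Converged per-sample MBAR weights W (N_total × K) plus counts.

    At the solution each column sums to 1 and, for every sample n,
    Σ_k N_k·W[n, k] = 1; both identities are enforced here to 1e-8.
    """

    W: np.ndarray
    N_k: StateCounts
    states: Optional[tuple[LambdaVector, ...]] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", w)
        nk = np.asarray(self.N_k.N_k, dtype=float)
        if w.ndim != 2 or w.shape[1] != len(nk):
            raise ValidationError(
                f"W must be N x {len(nk)}, got shape {w.shape}"
            )
        if w.shape[0]:
            col = w.sum(axis=0)
            if np.max(np.abs(col - 1.0)) > 1e-8:
                raise ValidationError(
                    f"unconverged weights: column sums deviate by "
                    f"{np.max(np.abs(col - 1.0)):.3g}"
                )
            row = w @ nk
            if np.max(np.abs(row - 1.0)) > 1e-8:
                raise ValidationError("weight row identity violated")


class BaseFreeEnergyEstimator(BaseEstimator):
    """Shared fit/attribute plumbing for all free-energy estimators."""

    _table_kind: type = object

    def fit(self, table, y=None):
        """Estimate free-energy differences from a standard table."""
        if not isinstance(table, self._table_kind):
            raise TypeError(
                f"{type(self).__name__}.fit expects a "
                f"{self._table_kind.__name__}, got {type(table).__name__}"
            )
        result = self._fit(table)
        self.result_ = result
        self.states_ = list(result.states)
        self.delta_f_ = result.delta_f_frame()
        self.d_delta_f_ = result.d_delta_f_frame()
        self.metadata_ = result.metadata
        return self

    def _fit(self, table) -> FreeEnergyResult:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# TI family
# ---------------------------------------------------------------------------

def _sorted_windows(dhdl: GradientTable):
    """Windows sorted lexicographically by λ-vector; duplicates are errors."""
    windows = dhdl.windows()
    windows.sort(key=lambda pair: pair[0].sort_key())
    for (a, _), (b, _) in zip(windows, windows[1:]):
        if a.values == b.values:
            raise EstimationError(f"duplicate lambda window {a}")
    return windows


def _window_moments(windows):
    """Per-window mean gradients and squared standard errors of the mean."""
    means, sem2, counts = [], [], []
    for lam, frame in windows:
        n = len(frame)
        if n < 2:
            raise EstimationError(
                f"window {lam} has {n} samples; need at least 2 for the SEM"
            )
        arr = frame.to_numpy(dtype=float)
        means.append(arr.mean(axis=0))
        sem2.append(arr.var(axis=0, ddof=1) / n)
        counts.append(n)
    return np.asarray(means), np.asarray(sem2), counts


def _changing_component(a: LambdaVector, b: LambdaVector) -> int:
    diffs = [
        i for i, (x, y) in enumerate(zip(a.values, b.values))
        if abs(x - y) > 1e-12
    ]
    if len(diffs) != 1:
        raise EstimationError(
            f"adjacent windows {a} -> {b} change {len(diffs)} components; "
            "the TI path requires exactly one per segment"
        )
    return diffs[0]


class TI(BaseFreeEnergyEstimator):
    """Thermodynamic integration by the trapezoid rule.

    Windows are sorted along the λ path; per segment exactly one
    component may change.  Δf between any two states integrates the
    window-mean gradients with trapezoid weights; the variance
    propagates the per-window standard errors of the mean through the
    same weights (windows are independent simulations).

    Fitted attributes include ``dhdl_means_`` and ``dhdl_sem_`` — the
    per-window mean gradients and their standard errors — consumed by
    the curvature diagnostic.
    """

    _table_kind = GradientTable

    def _fit(self, dhdl: GradientTable) -> FreeEnergyResult:
        windows = _sorted_windows(dhdl)
        if len(windows) < 2:
            raise EstimationError("TI needs at least 2 lambda windows")
        lams = [lam for lam, _ in windows]
        means, sem2, _ = _window_moments(windows)
        K, C = means.shape
        seg_comp = []
        seg_dlam = []
        for i in range(K - 1):
            c = _changing_component(lams[i], lams[i + 1])
            seg_comp.append(c)
            seg_dlam.append(lams[i + 1].values[c] - lams[i].values[c])
        delta_f = np.zeros((K, K))
        var = np.zeros((K, K))
        for a in range(K):
            for b in range(a + 1, K):
                w = np.zeros((K, C))
                df = 0.0
                for i in range(a, b):
                    c, dl = seg_comp[i], seg_dlam[i]
                    df += dl * (means[i, c] + means[i + 1, c]) / 2.0
                    w[i, c] += dl / 2.0
                    w[i + 1, c] += dl / 2.0
                v = float(np.sum(w**2 * sem2))
                delta_f[a, b] = df
                delta_f[b, a] = -df
                var[a, b] = var[b, a] = v
        result = FreeEnergyResult(
            states=tuple(lams),
            delta_f=delta_f,
            d_delta_f=np.sqrt(var),
            metadata=dhdl.metadata,
        )
        self.dhdl_means_ = pd.DataFrame(
            means, index=[l.values for l in lams], columns=list(lams[0].names)
        )
        self.dhdl_sem_ = pd.DataFrame(
            np.sqrt(sem2), index=[l.values for l in lams],
            columns=list(lams[0].names),
        )
        return result


def gauss_legendre_points(n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes and weights mapped from [−1, 1] to [0, 1]."""
    if not 1 <= n_points <= MAX_GAUSS_POINTS:
        raise ValueError(
            f"n_points must be in [1, {MAX_GAUSS_POINTS}], got {n_points}"
        )
    x, w = np.polynomial.legendre.leggauss(n_points)
    return (x + 1.0) / 2.0, w / 2.0


class GaussianQuadratureTI(BaseFreeEnergyEstimator):
    """TI with Gauss–Legendre quadrature over λ ∈ [0, 1].

    The sampled windows must sit on the n-point Gauss–Legendre nodes
    (mapped to [0, 1]) to within 1e-3 per varying component.  The
    endpoint free-energy difference is Σ_i w_i·⟨dH/dλ⟩_i with the mapped
    weights, and its variance Σ_i w_i²·SEM_i².  The result is reported
    between the two (unsampled) end states λ=0 and λ=1.

    Parameters
    ----------
    n_points : int, optional
        Number of quadrature nodes; inferred from the number of windows
        when omitted.  At most 16.
    """

    _table_kind = GradientTable

    def __init__(self, n_points: Optional[int] = None):
        self.n_points = n_points

    def _fit(self, dhdl: GradientTable) -> FreeEnergyResult:
        windows = _sorted_windows(dhdl)
        n = self.n_points if self.n_points is not None else len(windows)
        nodes, weights = gauss_legendre_points(n)
        if len(windows) != n:
            raise ValidationError(
                f"{n}-point quadrature needs exactly {n} windows, "
                f"got {len(windows)}"
            )
        lams = [lam for lam, _ in windows]
        values = np.asarray([lam.values for lam in lams])  # (n, C)
        spread = values.max(axis=0) - values.min(axis=0)
        varying = np.nonzero(spread > 1e-12)[0]
        if len(varying) == 0:
            varying = np.arange(values.shape[1])
        for c in varying:
            if np.max(np.abs(values[:, c] - nodes)) > NODE_MATCH_TOL:
                raise ValidationError(
                    f"window lambdas for component "
                    f"{lams[0].names[c]!r} do not match the {n}-point "
                    f"Gauss-Legendre nodes: expected {np.round(nodes, 6)}, "
                    f"got {values[:, c]}"
                )
        means, sem2, _ = _window_moments(windows)
        integrand = means[:, varying].sum(axis=1)
        int_sem2 = sem2[:, varying].sum(axis=1)
        df = float(np.sum(weights * integrand))
        var = float(np.sum(weights**2 * int_sem2))
        names = lams[0].names
        const = values[0]  # frozen components keep their value at the ends
        end0 = LambdaVector(
            names,
            tuple(0.0 if c in varying else const[c] for c in range(len(names))),
        )
        end1 = LambdaVector(
            names,
            tuple(1.0 if c in varying else const[c] for c in range(len(names))),
        )
        delta_f = np.array([[0.0, df], [-df, 0.0]])
        d = math.sqrt(var)
        d_delta_f = np.array([[0.0, d], [d, 0.0]])
        result = FreeEnergyResult(
            states=(end0, end1),
            delta_f=delta_f,
            d_delta_f=d_delta_f,
            metadata=dhdl.metadata,
        )
        self.nodes_ = nodes
        self.weights_ = weights
        self.dhdl_means_ = pd.DataFrame(
            means, index=[l.values for l in lams], columns=list(names)
        )
        return result


# ---------------------------------------------------------------------------
# FEP family
# ---------------------------------------------------------------------------

def _u_matrix(u_nk: ReducedPotentialTable):
    """(u, N_k, states, sample_state_index) in column-state order."""
    counts = state_counts(u_nk)
    states = u_nk.states()
    u = u_nk.data.to_numpy(dtype=float)
    value_to_col = {s.values: i for i, s in enumerate(states)}
    idx = u_nk.data.index
    tuples = zip(*[idx.get_level_values(i) for i in range(1, idx.nlevels)])
    origin = np.fromiter(
        (value_to_col[tuple(float(v) for v in t)] for t in tuples),
        dtype=np.int64,
        count=len(u_nk.data),
    )
    return u, counts, states, origin


class BAR(BaseFreeEnergyEstimator):
    """Bennett acceptance ratio over adjacent pairs of sampled states.

    For each pair (i, i+1) the Bennett self-consistent equation

        Σ_F fermi(M + w_F − Δf) = Σ_R fermi(−M + w_R + Δf),
        M = ln(n_F/n_R)

    is solved by bracketed root finding on the forward works
    w_F = u_{i+1} − u_i (samples of state i) and reverse works
    w_R = u_i − u_{i+1} (samples of state i+1); the variance is the
    Bennett asymptotic estimate.  Non-adjacent entries are path sums
    with variances added as if independent (an approximation: the path
    sum ignores the covariance introduced by shared intermediate
    states).

    Samples must exist for every column state — one-sided input (an
    unsampled state) is a hard error rather than a silent fall-back to
    exponential averaging, which has different bias.
    """

    _table_kind = ReducedPotentialTable

    def __init__(self, maximum_iterations: int = 10000,
                 relative_tolerance: float = 1e-10):
        self.maximum_iterations = maximum_iterations
        self.relative_tolerance = relative_tolerance

    def _fit(self, u_nk: ReducedPotentialTable) -> FreeEnergyResult:
        EstimatorConfig(self.maximum_iterations, self.relative_tolerance)
        u, counts, states, origin = _u_matrix(u_nk)
        K = len(states)
        if K < 2:
            raise EstimationError("BAR needs at least 2 states")
        for k, n in enumerate(counts.N_k):
            if n == 0:
                raise EstimationError(
                    f"state {states[k]} has no samples; BAR needs samples "
                    "from every state (one-sided estimation is not performed)"
                )
        seg_df = np.zeros(K - 1)
        seg_var = np.zeros(K - 1)
        for i in range(K - 1):
            w_f = u[origin == i, i + 1] - u[origin == i, i]
            w_r = u[origin == i + 1, i] - u[origin == i + 1, i + 1]
            if len(w_f) < 2 or len(w_r) < 2:
                raise EstimationError(
                    f"pair ({states[i]}, {states[i + 1]}) has too few samples "
                    "for the Bennett variance"
                )
            seg_df[i], seg_var[i] = self._solve_pair(w_f, w_r)
        delta_f = np.zeros((K, K))
        var = np.zeros((K, K))
        for a in range(K):
            for b in range(a + 1, K):
                df = float(seg_df[a:b].sum())
                v = float(seg_var[a:b].sum())
                delta_f[a, b], delta_f[b, a] = df, -df
                var[a, b] = var[b, a] = v
        return FreeEnergyResult(
            states=tuple(states),
            delta_f=delta_f,
            d_delta_f=np.sqrt(var),
            metadata=u_nk.metadata,
        )

    def _solve_pair(self, w_f: np.ndarray, w_r: np.ndarray):
        m = math.log(len(w_f) / len(w_r))

        def h(df: float) -> float:
            # strictly increasing in df; expit(-x) = 1/(1+exp(x))
            return float(
                np.sum(expit(-(m + w_f - df))) - np.sum(expit(-(-m + w_r + df)))
            )

        # initial guess: difference of exponential averages (stable)
        guess = 0.5 * (
            -(logsumexp(-w_f) - math.log(len(w_f)))
            + (logsumexp(-w_r) - math.log(len(w_r)))
        )
        lo = hi = guess
        span = 1.0
        for _ in range(200):
            lo, hi = guess - span, guess + span
            if h(lo) < 0 < h(hi):
                break
            span *= 2.0
        else:
            raise ConvergenceError(
                "could not bracket the Bennett root", last_iterate=guess
            )
        try:
            df = brentq(
                h, lo, hi,
                xtol=self.relative_tolerance,
                maxiter=self.maximum_iterations,
            )
        except RuntimeError as exc:
            raise ConvergenceError(str(exc), last_iterate=guess) from exc
        # Bennett asymptotic variance from the converged Fermi functions
        ff = expit(-(m + w_f - df))
        fr = expit(-(-m + w_r + df))
        var = (
            np.var(ff, ddof=0) / len(ff) / np.mean(ff) ** 2
            + np.var(fr, ddof=0) / len(fr) / np.mean(fr) ** 2
        )
        return float(df), float(var)


class MBAR(BaseFreeEnergyEstimator):
    """Multistate Bennett acceptance ratio.

    Solves the self-consistent equations

        f_k = −ln Σ_n exp(−u_k(x_n)) / (Σ_l N_l exp(f_l − u_l(x_n)))

    over the sampled states with log-sum-exp stabilization, anchored at
    f_0 = 0.  Iteration starts self-consistent and switches to Newton's
    method on the sampled free energies once the residual is small
    enough for its quadratic convergence to engage; if a Newton step
    misbehaves the solver falls back to self-consistent stepping.
    Unsampled column states receive free energies by a final
    perturbation step (they have no weight in the denominators).

    Uncertainties come from the asymptotic covariance Θ of the weight
    matrix: ``d_delta_f[i, j] = sqrt(Θ_ii + Θ_jj − 2Θ_ij)``.
    """

    _table_kind = ReducedPotentialTable

    def __init__(
        self,
        maximum_iterations: int = 10000,
        relative_tolerance: float = 1e-10,
        initial_free_energies: Optional[Sequence[float]] = None,
    ):
        self.maximum_iterations = maximum_iterations
        self.relative_tolerance = relative_tolerance
        self.initial_free_energies = initial_free_energies

    def _fit(self, u_nk: ReducedPotentialTable) -> FreeEnergyResult:
        EstimatorConfig(self.maximum_iterations, self.relative_tolerance)
        u, counts, states, _ = _u_matrix(u_nk)
        K = len(states)
        n_k = np.asarray(counts.N_k, dtype=float)
        if counts.N_total == 0:
            raise EstimationError("MBAR needs at least one sampled state")
        sampled = np.nonzero(n_k > 0)[0]
        f = np.zeros(K)
        if self.initial_free_energies is not None:
            init = np.asarray(self.initial_free_energies, dtype=float)
            if init.shape != (K,):
                raise ValueError(
                    f"initial_free_energies must have length {K}"
                )
            f = init.copy()
        f = self._solve(u, n_k, f, sampled)
        # one perturbation step assigns free energies to unsampled states;
        # sampled entries keep their converged values so the weight-matrix
        # identities hold to the solver tolerance
        log_denom = self._log_denominator(u, n_k, f, sampled)
        unsampled = np.nonzero(n_k == 0)[0]
        if len(unsampled):
            f[unsampled] = -logsumexp(
                -u[:, unsampled] - log_denom[:, None], axis=0
            )
        log_w = f[None, :] - u - log_denom[:, None]
        w = np.exp(log_w)
        f = f - f[0]
        theta = self._covariance(w, n_k)
        delta_f = f[None, :] - f[:, None]
        diag = np.diag(theta)
        var = diag[:, None] + diag[None, :] - 2.0 * theta
        d_delta_f = np.sqrt(np.clip(var, 0.0, None))
        np.fill_diagonal(d_delta_f, 0.0)
        d_delta_f = (d_delta_f + d_delta_f.T) / 2.0
        result = FreeEnergyResult(
            states=tuple(states),
            delta_f=delta_f - np.diag(np.diag(delta_f)),
            d_delta_f=d_delta_f,
            metadata=u_nk.metadata,
        )
        self.free_energies_ = f
        self.theta_ = theta
        self.weights_ = MbarWeights(W=w, N_k=counts, states=tuple(states))
        return result

    # -- solver internals --------------------------------------------------

    @staticmethod
    def _log_denominator(u, n_k, f, sampled):
        """log Σ_l N_l exp(f_l − u_nl) per sample, over sampled states."""
        log_n = np.log(n_k[sampled])
        return logsumexp(
            log_n[None, :] + f[sampled][None, :] - u[:, sampled], axis=1
        )

    def _solve(self, u, n_k, f, sampled):
        """Iterate to self-consistency; returns converged f (unanchored).

        Convergence is measured on the self-consistency residual
        max_k |Σ_n W_nk − 1| over sampled states, which is scale-free
        and guarantees the weight-matrix column sums to the same
        tolerance.  Self-consistent steps (f_k ← f_k − ln Σ_n W_nk) run
        until the residual is small, then Newton on the sampled free
        energies finishes quadratically; rejected Newton steps fall
        back to self-consistent stepping.
        """
        rtol = self.relative_tolerance
        newton_ok = len(sampled) > 1
        use_newton = False
        residual = math.inf
        for iteration in range(self.maximum_iterations):
            log_denom = self._log_denominator(u, n_k, f, sampled)
            log_col = logsumexp(
                f[sampled][None, :] - u[:, sampled] - log_denom[:, None],
                axis=0,
            )
            residual = float(np.max(np.abs(np.expm1(log_col))))
            if residual <= rtol:
                return f
            if residual <= 1e-2:
                use_newton = True  # close enough for quadratic convergence
            f_new = None
            if use_newton and newton_ok:
                f_new = self._newton_step(u, n_k, f, sampled, log_denom)
            if f_new is None:
                f_new = f.copy()
                f_new[sampled] = f[sampled] - log_col  # self-consistent step
            f = f_new
        raise ConvergenceError(
            f"MBAR did not converge in {self.maximum_iterations} iterations "
            f"(final self-consistency residual {residual:.3g})",
            last_iterate=f,
        )

    def _newton_step(self, u, n_k, f, sampled, log_denom):
        log_w = f[sampled][None, :] - u[:, sampled] - log_denom[:, None]
        w = np.exp(log_w)  # N x Ks, unit column sums at the solution
        ns = n_k[sampled]
        s = w.sum(axis=0)
        grad = ns * (s - 1.0)
        hess = np.diag(ns * s) - (ns[:, None] * ns[None, :]) * (w.T @ w)
        free = np.arange(1, len(sampled))  # anchor the first sampled state
        try:
            delta = np.linalg.solve(hess[np.ix_(free, free)], -grad[free])
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(delta)) or np.max(np.abs(delta)) > 10.0:
            return None  # reject wild steps; fall back to SCF
        f_new = f.copy()
        f_new[sampled[free]] = f_new[sampled[free]] + delta
        f_new = f_new - f_new[sampled[0]]
        return f_new

    @staticmethod
    def _covariance(w, n_k):
        """Asymptotic covariance Θ of the free energies from W (SVD form)."""
        u_svd, s, vt = np.linalg.svd(w, full_matrices=False)
        k = w.shape[1]
        inner = np.eye(k) - (s[:, None] * vt) @ np.diag(n_k) @ (vt.T * s[None, :])
        inner_inv = np.linalg.pinv(inner, rcond=1e-12, hermitian=True)
        return (vt.T * s[None, :]) @ inner_inv @ (s[:, None] * vt)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def ti_fit(dhdl: GradientTable) -> FreeEnergyResult:
    """Trapezoid-rule TI; see :class:`TI`."""
    return TI().fit(dhdl).result_


def ti_gauss_fit(dhdl: GradientTable, n_points: Optional[int] = None
                 ) -> FreeEnergyResult:
    """Gauss–Legendre TI; see :class:`GaussianQuadratureTI`."""
    return GaussianQuadratureTI(n_points=n_points).fit(dhdl).result_


def bar_fit(u_nk: ReducedPotentialTable,
            config: Optional[EstimatorConfig] = None) -> FreeEnergyResult:
    """Bennett acceptance ratio; see :class:`BAR`."""
    config = config or EstimatorConfig()
    est = BAR(
        maximum_iterations=config.maximum_iterations,
        relative_tolerance=config.relative_tolerance,
    )
    return est.fit(u_nk).result_


def mbar_fit(u_nk: ReducedPotentialTable,
             config: Optional[EstimatorConfig] = None
             ) -> tuple[FreeEnergyResult, MbarWeights]:
    """Multistate BAR; see :class:`MBAR`."""
    config = config or EstimatorConfig()
    est = MBAR(
        maximum_iterations=config.maximum_iterations,
        relative_tolerance=config.relative_tolerance,
        initial_free_energies=config.initial_free_energies,
    )
    est.fit(u_nk)
    return est.result_, est.weights_
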