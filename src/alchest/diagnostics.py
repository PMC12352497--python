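"""Quality diagnostics for free-energy estimates.

Free-energy numbers mean little without evidence that the underlying
sampling supports them.  This module computes the standard numeric
checks; each has an optional plot twin in :mod:`alchest.visualization`,
but the tables here are the tested artifacts.

* :func:`overlap_matrix` — the row-stochastic phase-space overlap matrix
  O[i, j] = N_j·Σ_n W[n, i]·W[n, j] built from converged MBAR weights;
  vanishing off-diagonals between neighboring states signal that FEP
  estimates bridge essentially disjoint distributions.
* :func:`forward_backward_convergence` — the endpoint estimate as a
  function of the fraction of simulation time used, computed forward
  from the start and backward from the end; persistent disagreement
  indicates unequilibrated or drifting data.
* :func:`fractional_equilibration` — per-window t0/T from automated
  equilibration detection, flagged above a threshold.
* :func:`ti_curvature_profile` — second differences of the mean TI
  integrand over λ; large curvature is where the trapezoid rule loses
  accuracy and windows should be added.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datamodel import GradientTable, LambdaVector
from .estimators import (
    BAR,
    MBAR,
    TI,
    GaussianQuadratureTI,
    MbarWeights,
)
from .exceptions import EstimationError, ValidationError
from .preprocessing import _series_for_policy, detect_equilibration

__all__ = [
    "OverlapMatrix",
    "ConvergenceSeries",
    "EquilibrationSummary",
    "WindowEquilibration",
    "overlap_matrix",
    "forward_backward_convergence",
    "fractional_equilibration",
    "ti_curvature_profile",
]

ESTIMATORS = {
    "TI": TI,
    "TI-GQ": GaussianQuadratureTI,
    "BAR": BAR,
    "MBAR": MBAR,
}


@dataclass(frozen=True)
class OverlapMatrix:
    """Row-stochastic phase-space overlap between sampled states."""

    O: np.ndarray
    states: tuple[LambdaVector, ...]

    def __post_init__(self) -> None:
        o = np.asarray(self.O, dtype=float)
        object.__setattr__(self, "O", o)
        object.__setattr__(self, "states", tuple(self.states))
        k = len(self.states)
        if o.shape != (k, k):
            raise ValidationError(f"overlap matrix must be {k}x{k}")
        if np.any(o < -1e-12) or np.any(o > 1 + 1e-12):
            raise ValidationError("overlap entries must lie in [0, 1]")
        if k and np.max(np.abs(o.sum(axis=1) - 1.0)) > 1e-8:
            raise ValidationError("overlap rows must sum to 1")


@dataclass(frozen=True)
class ConvergenceSeries:
    """Endpoint Δf (kT) vs fraction of simulation time, both directions."""

    fractions: tuple[float, ...]
    forward_df: tuple[float, ...]
    forward_err: tuple[float, ...]
    backward_df: tuple[float, ...]
    backward_err: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.fractions)
        for name in ("forward_df", "forward_err", "backward_df", "backward_err"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length != {n}")
        if n == 0 or abs(self.fractions[-1] - 1.0) > 1e-12:
            raise ValidationError("last fraction must be 1")
        if abs(self.forward_df[-1] - self.backward_df[-1]) > 1e-10:
            raise ValidationError(
                "forward and backward estimates must coincide at fraction 1"
            )


@dataclass(frozen=True)
class WindowEquilibration:
    """Equilibration diagnosis of one λ-window."""

    state: LambdaVector
    fraction_equilibration: Optional[float]
    flagged: bool
    error: Optional[str] = None


@dataclass(frozen=True)
class EquilibrationSummary:
    """Per-window fractional equilibration times with flags."""

    windows: tuple[WindowEquilibration, ...]
    threshold: float

    def any_flagged(self) -> bool:
        return any(w.flagged for w in self.windows)


def overlap_matrix(weights: MbarWeights) -> OverlapMatrix:
    """Phase-space overlap O[i, j] = N_j·Σ_n W[n, i]·W[n, j].

    Rows sum to 1 by the converged-weight identities; entry [i, j] is
    the probability that a sample drawn from state i would be "seen" by
    state j's distribution.  *weights* must come from a converged MBAR
    fit (column sums are re-validated by :class:`MbarWeights`).
    """
    w = weights.W
    n_k = np.asarray(weights.N_k.N_k, dtype=float)
    o = (w.T @ w) * n_k[None, :]
    states = weights.states
    if states is None:
        k = len(n_k)
        states = tuple(
            LambdaVector(("state",), (i / max(1, k - 1),)) for i in range(k)
        )
    return OverlapMatrix(O=o, states=states)


def _fit_endpoint(table, estimator_name: str):
    cls = ESTIMATORS.get(estimator_name)
    if cls is None:
        raise ValueError(
            f"unknown estimator {estimator_name!r}; expected one of "
            f"{sorted(ESTIMATORS)}"
        )
    est = cls().fit(table)
    return est.result_.endpoint()


def forward_backward_convergence(
    table, estimator_name: str = "MBAR", n_fractions: int = 10
) -> ConvergenceSeries:
    """Endpoint Δf from growing forward and backward data fractions.

    For i = 1..n_fractions the forward estimate uses the first
    ⌊i·n/n_fractions⌋ rows of each window and the backward estimate the
    last as many; fractions are per-window row counts, so unequal window
    lengths are handled.  At fraction 1 both directions equal the
    full-data estimate exactly.
    """
    n_fractions = int(n_fractions)
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if estimator_name not in ESTIMATORS:
        raise ValueError(
            f"unknown estimator {estimator_name!r}; expected one of "
            f"{sorted(ESTIMATORS)}"
        )
    windows = table.windows()
    for lam, frame in windows:
        if len(frame) < n_fractions:
            raise ValueError(
                f"window {lam} has {len(frame)} rows < n_fractions="
                f"{n_fractions}"
            )
    from .preprocessing import _reassemble

    fractions, fwd, fwd_e, bwd, bwd_e = [], [], [], [], []
    for i in range(1, n_fractions + 1):
        frac = i / n_fractions
        fw_pieces = []
        bw_pieces = []
        for lam, frame in windows:
            m = math.floor(frac * len(frame))
            fw_pieces.append((lam, frame.iloc[:m]))
            bw_pieces.append((lam, frame.iloc[len(frame) - m:]))
        try:
            df_f, err_f = _fit_endpoint(_reassemble(table, fw_pieces),
                                        estimator_name)
            df_b, err_b = _fit_endpoint(_reassemble(table, bw_pieces),
                                        estimator_name)
        except Exception as exc:
            raise EstimationError(
                f"{estimator_name} failed at fraction {frac:g}: {exc}"
            ) from exc
        fractions.append(frac)
        fwd.append(df_f)
        fwd_e.append(err_f)
        bwd.append(df_b)
        bwd_e.append(err_b)
    return ConvergenceSeries(
        fractions=tuple(fractions),
        forward_df=tuple(fwd),
        forward_err=tuple(fwd_e),
        backward_df=tuple(bwd),
        backward_err=tuple(bwd_e),
    )


def fractional_equilibration(
    table, threshold: float = 0.3, series_policy: Optional[str] = None,
    column=None,
) -> EquilibrationSummary:
    """Per-window fractional equilibration time t0/T, with flags.

    The correlation series of each window (same policies as
    :func:`alchest.preprocessing.decorrelate`) is run through automated
    equilibration detection; windows whose equilibrated-away fraction
    exceeds *threshold* are flagged.  A window too short to analyze gets
    a per-window error entry rather than failing the whole table.
    """
    if series_policy is None:
        series_policy = (
            "gradient-sum" if isinstance(table, GradientTable)
            else "neighbor-difference"
        )
    entries = []
    for lam, frame in table.windows():
        try:
            series = _series_for_policy(table, lam, frame, series_policy,
                                        column)
            t0, _, _ = detect_equilibration(series)
        except Exception as exc:
            entries.append(
                WindowEquilibration(
                    state=lam, fraction_equilibration=None, flagged=False,
                    error=str(exc),
                )
            )
            continue
        fraction = t0 / len(series)
        entries.append(
            WindowEquilibration(
                state=lam,
                fraction_equilibration=fraction,
                flagged=fraction > threshold,
            )
        )
    return EquilibrationSummary(windows=tuple(entries), threshold=threshold)


def ti_curvature_profile(ti_estimator) -> dict:
    """Second-difference curvature summary of the TI integrand.

    Takes a fitted :class:`~alchest.estimators.TI` (or compatible)
    estimator and returns the absolute second central differences of the
    per-window mean gradients along λ (summed over components), plus
    their mean — the numeric twin of the integrand-smoothness plot.
    Large values mark λ-regions where the trapezoid rule is inaccurate.
    """
    means = getattr(ti_estimator, "dhdl_means_", None)
    if means is None:
        raise ValueError("ti_curvature_profile needs a fitted TI estimator")
    m = means.to_numpy(dtype=float).sum(axis=1)
    if len(m) < 3:
        raise ValueError(
            f"curvature needs at least 3 windows, got {len(m)}"
        )
    second = np.abs(m[2:] - 2.0 * m[1:-1] + m[:-2])
    return {
        "second_differences": second,
        "mean_curvature": float(second.mean()),
    }
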