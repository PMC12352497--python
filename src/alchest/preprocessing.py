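"""Slicing, decorrelation and equilibration detection.

Free-energy estimators assume statistically independent samples, but MD
and MC trajectories are autocorrelated and often begin far from
equilibrium.  This module provides the standard remedies:

* :func:`slice_table` — plain time-range/stride slicing;
* :func:`statistical_inefficiency` — the factor g ≥ 1 by which
  autocorrelation inflates the variance of a sample mean, estimated from
  the normalized autocovariance summed to its first non-positive lag;
* :func:`detect_equilibration` — chooses the equilibration start t0 that
  maximizes the number of effective samples (T − t0)/g of the remainder;
* :func:`decorrelate` — trims each window at its detected t0 and keeps
  every ⌈g⌉-th frame thereafter, returning the subsampled table plus a
  per-window :class:`DecorrelationReport`.

Everything here is deterministic: no randomness is involved anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GradientTable, LambdaVector, ReducedPotentialTable
from .exceptions import PolicyError

logger = logging.getLogger(__name__)

__all__ = [
    "DecorrelationReport",
    "slice_table",
    "statistical_inefficiency",
    "detect_equilibration",
    "decorrelate",
    "subsample_indices",
]

#: above this series length the equilibration search uses a coarse grid
FULL_SCAN_MAX = 2000

#: number of candidate origins on the coarse grid
N_GRID = 100


@dataclass(frozen=True)
class DecorrelationReport:
    """Outcome of equilibration detection + subsampling for one window."""

    t0: int
    g: float
    n_effective: float
    kept_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if self.g < 1.0:
            raise ValueError(f"g must be >= 1, got {self.g}")
        kept = self.kept_indices
        if any(b <= a for a, b in zip(kept, kept[1:])) or (
            kept and kept[0] < self.t0
        ):
            raise ValueError("kept_indices must be strictly increasing and >= t0")

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)


def slice_table(table, lower: float = -math.inf, upper: float = math.inf,
                step: int = 1):
    """Keep rows with ``lower <= time <= upper``, then every *step*-th.

    The stride is applied per window after the time filter, so unequal
    window lengths are handled independently.  An empty result for a
    window (e.g. ``lower`` beyond its last frame) is allowed.
    """
    step = int(step)
    if step < 1:
        raise ValueError(f"step must be a positive integer, got {step}")
    if lower > upper:
        raise ValueError(f"lower={lower} > upper={upper}")
    pieces = []
    for lam, frame in table.windows():
        times = frame.index.to_numpy(dtype=float)
        mask = (times >= lower) & (times <= upper)
        sub = frame.loc[mask].iloc[::step]
        pieces.append((lam, sub))
    return _reassemble(table, pieces)


def _reassemble(table, pieces):
    """Rebuild a table of the same kind from per-window frames."""
    names = table.lambda_names
    frames = []
    for lam, frame in pieces:
        idx = pd.MultiIndex.from_arrays(
            [frame.index.to_numpy(dtype=float)]
            + [np.full(len(frame), v) for v in lam.values],
            names=["time", *names],
        )
        f = frame.copy()
        f.index = idx
        frames.append(f)
    if frames:
        data = pd.concat(frames, axis=0)
    else:
        data = table.data.iloc[0:0]
    if isinstance(table, ReducedPotentialTable):
        data.columns = pd.Index(list(table.data.columns), tupleize_cols=False)
    return table._replace(data)


def _normalized_autocovariance(x: np.ndarray) -> np.ndarray:
    """Ĉ(t) for t = 0..n−1 via FFT, Ĉ(0) = 1; zero-variance gives NaNs."""
    n = len(x)
    x = np.asarray(x, dtype=float) - np.mean(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n]
    if acov[0] <= 0:
        return np.full(n, np.nan)
    return acov / acov[0]


def statistical_inefficiency(series) -> float:
    """Statistical inefficiency g of a scalar time series.

    g = 1 + 2·Σ_{t=1}^{t_cut} (1 − t/T)·Ĉ(t), where Ĉ is the normalized
    autocovariance and t_cut is the first lag with Ĉ(t) ≤ 0 (that final,
    non-positive term included).  The result is clamped to ≥ 1; for an
    uncorrelated series g → 1 and the effective sample size is T/g.
    A zero-variance (constant) series returns 1 with a warning.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if n < 2:
        raise ValueError(f"need at least 2 samples, got {n}")
    c = _normalized_autocovariance(x)
    if np.isnan(c[0]):
        logger.warning(
            "statistical_inefficiency: zero-variance series, returning g = 1"
        )
        return 1.0
    tail = c[1:]
    nonpos = np.nonzero(tail <= 0)[0]
    t_cut = int(nonpos[0]) + 1 if len(nonpos) else n - 1
    t = np.arange(1, t_cut + 1)
    g = 1.0 + 2.0 * np.sum((1.0 - t / n) * c[1 : t_cut + 1])
    return max(1.0, float(g))


def detect_equilibration(series) -> tuple[int, float, float]:
    """Pick the equilibration start that maximizes effective samples.

    Scans candidate origins t0 and returns the triple
    ``(t0, g(series[t0:]), (T − t0)/g)`` with the largest effective
    sample count.  All origins are scanned for short series
    (n ≤ 2000); longer series use 100 evenly spaced candidates.
    t0 = 0 is always among the candidates, so the result is never worse
    than no trimming at all.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = len(x)
    if n < 4:
        raise ValueError(f"need at least 4 samples, got {n}")
    if n <= FULL_SCAN_MAX:
        candidates = np.arange(0, n - 1)
    else:
        candidates = np.unique(
            np.linspace(0, n - 2, N_GRID).astype(int)
        )
    best = (0, math.inf, -math.inf)  # (t0, g, n_eff)
    for t0 in candidates:
        m = n - t0
        if m < 2:
            continue
        g = statistical_inefficiency(x[t0:])
        n_eff = m / g
        if n_eff > best[2]:
            best = (int(t0), g, n_eff)
    return best


def subsample_indices(t0: int, g: float, n: int) -> tuple[int, ...]:
    """Indices t0, t0+⌈g⌉, t0+2⌈g⌉, … below n (conservative stride)."""
    stride = max(1, math.ceil(g - 1e-12))
    return tuple(range(int(t0), int(n), stride))


def _series_for_policy(table, lam, frame, policy, column):
    if policy == "explicit-column":
        if column is None:
            raise PolicyError("explicit-column policy needs a column name")
        return frame[column].to_numpy(dtype=float)
    if isinstance(table, GradientTable):
        if policy != "gradient-sum":
            raise PolicyError(
                f"policy {policy!r} does not apply to a GradientTable"
            )
        return frame.to_numpy(dtype=float).sum(axis=1)
    if policy != "neighbor-difference":
        raise PolicyError(
            f"policy {policy!r} does not apply to a ReducedPotentialTable"
        )
    cols = list(table.data.columns)
    if len(cols) < 2:
        raise PolicyError(
            "neighbor-difference needs at least two evaluated states"
        )
    i = cols.index(lam.values)
    j = i + 1 if i + 1 < len(cols) else i - 1
    return (frame[cols[j]] - frame[cols[i]]).to_numpy(dtype=float)


def decorrelate(table, series_policy: str | None = None, column=None):
    """Equilibrate-trim and subsample every window of a table.

    Per window a scalar correlation series is built according to
    *series_policy* (default: ``gradient-sum`` for gradient tables —
    the TI integrand — and ``neighbor-difference`` for reduced-potential
    tables — u at the next state minus u at the own state, the FEP
    work observable; the last window uses its previous neighbor).
    :func:`detect_equilibration` then fixes t0 and g, and frames
    t0, t0+⌈g⌉, t0+2⌈g⌉, … are kept.

    Returns ``(subsampled_table, reports)`` where *reports* maps each
    window's :class:`~alchest.datamodel.LambdaVector` to its
    :class:`DecorrelationReport`.  Rows are never reordered and never
    mixed across windows.
    """
    if series_policy is None:
        series_policy = (
            "gradient-sum" if isinstance(table, GradientTable)
            else "neighbor-difference"
        )
    if series_policy not in ("gradient-sum", "neighbor-difference",
                             "explicit-column"):
        raise PolicyError(f"unknown series policy {series_policy!r}")
    pieces = []
    reports: dict[LambdaVector, DecorrelationReport] = {}
    for lam, frame in table.windows():
        series = _series_for_policy(table, lam, frame, series_policy, column)
        t0, g, n_eff = detect_equilibration(series)
        kept = subsample_indices(t0, g, len(frame))
        reports[lam] = DecorrelationReport(
            t0=t0, g=g, n_effective=n_eff, kept_indices=kept
        )
        pieces.append((lam, frame.iloc[list(kept)]))
    return _reassemble(table, pieces), reports
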