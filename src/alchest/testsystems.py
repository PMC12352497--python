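"""Synthetic harmonic λ-path with analytically known free energies.

The generator emulates a stratified alchemical calculation on the
simplest system with a closed-form answer: a one-dimensional harmonic
potential U_λ(x) = K(λ)·x²/2 whose force constant interpolates linearly
between the end states, K(λ) = (1−λ)·K0 + λ·K1.  In reduced (β = 1)
units the free energy of state k is −½·ln(2π/K(λ_k)) up to a constant,
so every estimator target is known exactly:

    f_k − f_0 = ½·ln(K(λ_k)/K0),   Δf(0→1) = ½·ln(K1/K0)

and the TI integrand ⟨dH/dλ⟩ = (K1−K0)/(2K(λ)) integrates to the same
number — the TI and FEP targets agree by construction.

Sampling emulates the two awkward features of real MD time series:

* **autocorrelation** — x_t follows a stationary AR(1) process whose
  coefficient is chosen so that the *observables* (x²-based gradients
  and reduced potentials) have lag-1 autocorrelation φ, hence a
  statistical inefficiency of (1+φ)/(1−φ); for a Gaussian AR(1) with
  coefficient ρ the squared process decays as ρ², so x is generated
  with coefficient √φ;
* **unequilibrated transients** — an optional ``burn_shift`` offsets
  the first fraction of each window by a multiple of the stationary
  standard deviation, which equilibration detection should trim.

What it does *not* emulate: multidimensional configurations, soft-core
λ-dependence, anharmonicity, or correlated windows.  Passing tests on
this system demonstrate estimator and pipeline correctness, not
robustness to force-field pathologies.

Defaults are the library's reference study conditions: K0 = 1, K1 = 4,
nine evenly spaced windows, 10000 raw samples per window at φ = 0.25
(observable g = 5/3, subsampling stride ⌈g⌉ = 2, hence ≈5000
decorrelated samples per window), tagged kT at a nominal 300 K so the
unit pipeline is exercised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .datamodel import (
    EnergyMetadata,
    GradientTable,
    LambdaVector,
    ReducedPotentialTable,
    kt_to_kj_per_mol,
)
from .estimators import gauss_legendre_points
from .parsers import write_csv

__all__ = ["HarmonicSpec", "exact_free_energies", "sample",
           "write_fixtures"]

_DEFAULT_LAMBDAS = tuple(np.linspace(0.0, 1.0, 9))


@dataclass(frozen=True)
class HarmonicSpec:
    """Parameters of the synthetic harmonic λ-path.

    ``burn_shift`` is a ``(fraction, offset)`` pair: the first
    *fraction* of each window is displaced by *offset* stationary
    standard deviations.  ``frozen_component`` optionally adds a second
    λ-component held at a constant value (zero gradient) to exercise
    multi-component bookkeeping.
    """

    K0: float = 1.0
    K1: float = 4.0
    lambdas: tuple[float, ...] = _DEFAULT_LAMBDAS
    n_samples: int = 10000
    phi: float = 0.25
    burn_shift: Optional[tuple[float, float]] = None
    seed: int = 0
    temperature: float = 300.0
    component: str = "fep-lambda"
    frozen_component: Optional[tuple[str, float]] = None
    require_endpoints: bool = True

    def __post_init__(self) -> None:
        lambdas = tuple(float(v) for v in self.lambdas)
        object.__setattr__(self, "lambdas", lambdas)
        if self.K0 <= 0 or self.K1 <= 0:
            raise ValueError("force constants must be positive")
        if any(b <= a for a, b in zip(lambdas, lambdas[1:])):
            raise ValueError("lambdas must be strictly increasing")
        if any(not 0.0 <= v <= 1.0 for v in lambdas):
            raise ValueError("lambdas must lie in [0, 1]")
        if self.require_endpoints and (
            lambdas[0] != 0.0 or lambdas[-1] != 1.0
        ):
            raise ValueError(
                "lambdas must contain the end states 0 and 1 "
                "(pass require_endpoints=False for quadrature-node layouts)"
            )
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError(f"AR(1) coefficient phi={self.phi} not in [0, 1)")
        if self.burn_shift is not None:
            frac, _ = self.burn_shift
            if not 0.0 <= frac < 1.0:
                raise ValueError("burn fraction must be in [0, 1)")

    @classmethod
    def gauss_legendre(cls, n_points: int, **kwargs) -> "HarmonicSpec":
        """Spec with windows on the n-point Gauss–Legendre nodes."""
        nodes, _ = gauss_legendre_points(n_points)
        kwargs.setdefault("require_endpoints", False)
        return cls(lambdas=tuple(nodes), **kwargs)

    def force_constants(self) -> np.ndarray:
        lam = np.asarray(self.lambdas)
        return (1.0 - lam) * self.K0 + lam * self.K1

    @property
    def analytic_delta_f(self) -> float:
        """Exact Δf(λ=0 → λ=1) = ½·ln(K1/K0) in kT."""
        return 0.5 * math.log(self.K1 / self.K0)

    def lambda_vector(self, value: float) -> LambdaVector:
        if self.frozen_component is None:
            return LambdaVector((self.component,), (value,))
        name, frozen = self.frozen_component
        return LambdaVector((self.component, name), (value, frozen))


def exact_free_energies(spec: HarmonicSpec) -> np.ndarray:
    """Analytic f_k − f_0 = ½·ln(K(λ_k)/K0) per window, in kT."""
    k = spec.force_constants()
    return 0.5 * np.log(k / k[0])


def _ar1(rng: np.random.Generator, n: int, sigma: float, phi: float
         ) -> np.ndarray:
    """Stationary AR(1) series with marginal std *sigma*."""
    eps = rng.standard_normal(n)
    innovations = eps * (sigma * math.sqrt(1.0 - phi * phi))
    innovations[0] = eps[0] * sigma  # start from the stationary distribution
    return lfilter([1.0], [1.0, -phi], innovations)


def sample(spec: HarmonicSpec) -> tuple[GradientTable, ReducedPotentialTable]:
    """Draw per-window trajectories and fill both table kinds.

    Per window k the configuration x_t is an AR(1)-correlated Gaussian
    with stationary variance 1/K(λ_k) and coefficient √φ (so the
    observables decay with lag-1 autocorrelation φ); the gradient
    column holds dH/dλ = (K1−K0)·x²/2 and the reduced-potential columns
    u_j(x) = K(λ_j)·x²/2 for every window j.  Deterministic under the
    spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    rho = math.sqrt(spec.phi)
    k_all = spec.force_constants()
    names = spec.lambda_vector(0.0).names
    time = np.arange(spec.n_samples, dtype=float)
    dk = spec.K1 - spec.K0
    dhdl_frames = []
    unk_frames = []
    columns = [spec.lambda_vector(v).values for v in spec.lambdas]
    for lam_value, k_window in zip(spec.lambdas, k_all):
        sigma = 1.0 / math.sqrt(k_window)
        x = _ar1(rng, spec.n_samples, sigma, rho)
        if spec.burn_shift is not None:
            frac, offset = spec.burn_shift
            m = int(math.floor(frac * spec.n_samples))
            x[:m] += offset * sigma
        x2 = x * x
        lam = spec.lambda_vector(lam_value)
        index = pd.MultiIndex.from_arrays(
            [time] + [np.full(spec.n_samples, v) for v in lam.values],
            names=["time", *names],
        )
        grad = {spec.component: dk * x2 / 2.0}
        if spec.frozen_component is not None:
            grad[spec.frozen_component[0]] = np.zeros(spec.n_samples)
        dhdl_frames.append(pd.DataFrame(grad, index=index))
        u = {col: kj * x2 / 2.0 for col, kj in zip(columns, k_all)}
        frame = pd.DataFrame(u, index=index)
        frame.columns = pd.Index(columns, tupleize_cols=False)
        unk_frames.append(frame)
    metadata = EnergyMetadata(spec.temperature, "kT")
    dhdl_data = pd.concat(dhdl_frames, axis=0)
    unk_data = pd.concat(unk_frames, axis=0)
    unk_data.columns = pd.Index(columns, tupleize_cols=False)
    return (
        GradientTable(dhdl_data, metadata),
        ReducedPotentialTable(unk_data, metadata),
    )


# ---------------------------------------------------------------------------
# fixture writing (CSV dialect and GROMACS-style XVG)
# ---------------------------------------------------------------------------

def _xvg_window(spec: HarmonicSpec, lam: LambdaVector,
                dhdl_frame: pd.DataFrame, unk_frame: pd.DataFrame,
                columns) -> str:
    """One combined dH/dλ + ΔH XVG document, energies in kJ/mol."""
    kt = kt_to_kj_per_mol(spec.temperature)
    lines = [
        "# synthetic harmonic window written by alchest.testsystems",
        '@    title "dH/d\\xl\\f{} and \\xD\\f{}H"',
        f'@    subtitle "T = {spec.temperature:g} (K)"',
        '@    xaxis  label "Time (ps)"',
        '@    yaxis  label "dH/d\\xl\\f{} and \\xD\\f{}H (kJ/mol)"',
    ]
    legends = []
    for name, value in zip(lam.names, lam.values):
        legends.append(f'dH/d\\xl\\f{{}} {name} = {value:.17g}')
    for col in columns:
        if len(col) == 1:
            target = f"{col[0]:.17g}"
        else:
            target = "(" + ", ".join(f"{v:.17g}" for v in col) + ")"
        legends.append(f'\\xD\\f{{}}H \\xl\\f{{}} to {target}')
    for i, legend in enumerate(legends):
        lines.append(f'@ s{i} legend "{legend}"')
    times = dhdl_frame.index.to_numpy(dtype=float)
    grad = dhdl_frame.to_numpy(dtype=float) * kt
    u = unk_frame.to_numpy(dtype=float) * kt
    for r in range(len(times)):
        fields = [f"{times[r]:.17g}"]
        fields += [f"{v:.17g}" for v in grad[r]]
        fields += [f"{v:.17g}" for v in u[r]]
        lines.append(" ".join(fields))
    return "\n".join(lines) + "\n"


def write_fixtures(spec: HarmonicSpec, directory, fmt: str = "csv"
                   ) -> dict:
    """Write per-window fixture files plus a manifest with exact answers.

    ``fmt="csv"`` writes one alchest-CSV pair per window
    (``window_NN.dhdl.csv`` / ``window_NN.u_nk.csv``); ``fmt="xvg"``
    writes one combined GROMACS-style file per window
    (``window_NN.xvg``) with energies in kJ/mol.  Returns the manifest
    dictionary (also stored as ``manifest.json``).
    """
    if fmt not in ("csv", "xvg"):
        raise ValueError(f"unknown fixture format {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dhdl, u_nk = sample(spec)
    paths = []
    metadata = EnergyMetadata(spec.temperature, "kT")
    columns = list(u_nk.data.columns)
    for i, ((lam, dframe), (_, uframe)) in enumerate(
        zip(dhdl.windows(), u_nk.windows())
    ):
        if fmt == "csv":
            dp = directory / f"window_{i:02d}.dhdl.csv"
            up = directory / f"window_{i:02d}.u_nk.csv"
            write_csv(_single_window(dhdl, lam, dframe, metadata), dp)
            write_csv(_single_window(u_nk, lam, uframe, metadata), up)
            paths += [str(dp), str(up)]
        else:
            p = directory / f"window_{i:02d}.xvg"
            p.write_text(_xvg_window(spec, lam, dframe, uframe, columns))
            paths.append(str(p))
    manifest = {
        "spec": {
            "K0": spec.K0, "K1": spec.K1, "lambdas": list(spec.lambdas),
            "n_samples": spec.n_samples, "phi": spec.phi,
            "burn_shift": list(spec.burn_shift) if spec.burn_shift else None,
            "seed": spec.seed, "temperature": spec.temperature,
        },
        "format": fmt,
        "files": paths,
        "exact_free_energies_kT": [float(v) for v in exact_free_energies(spec)],
        "analytic_delta_f_kT": spec.analytic_delta_f,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _single_window(table, lam, frame, metadata):
    idx = pd.MultiIndex.from_arrays(
        [frame.index.to_numpy(dtype=float)]
        + [np.full(len(frame), v) for v in lam.values],
        names=["time", *lam.names],
    )
    data = frame.copy()
    data.index = idx
    if isinstance(table, ReducedPotentialTable):
        data.columns = pd.Index(list(table.data.columns), tupleize_cols=False)
        return ReducedPotentialTable(data, metadata)
    return GradientTable(data, metadata)
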