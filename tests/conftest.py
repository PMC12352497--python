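"""Shared builders and fixtures for the test suite.

All fixture data is generated programmatically — either through the
synthetic harmonic test system (analytically known answers) or through
the small builders below that assemble tables directly from arrays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from alchest.datamodel import (
    EnergyMetadata,
    GradientTable,
    ReducedPotentialTable,
)


def make_dhdl(window_values, lambdas, names=("fep-lambda",),
              temperature=300.0, unit="kT"):
    """GradientTable from per-window gradient arrays.

    ``window_values[k]`` is an (n, C) or (n,) array of gradient samples
    for the window at ``lambdas[k]`` (scalar λ or tuple).
    """
    frames = []
    for lam, vals in zip(lambdas, window_values):
        vals = np.atleast_2d(np.asarray(vals, dtype=float))
        if vals.shape[0] == 1 and vals.shape[1] != len(names):
            vals = vals.T
        lam_t = lam if isinstance(lam, tuple) else (lam,)
        n = vals.shape[0]
        idx = pd.MultiIndex.from_arrays(
            [np.arange(n, dtype=float)]
            + [np.full(n, v) for v in lam_t],
            names=["time", *names],
        )
        frames.append(pd.DataFrame(vals, index=idx, columns=list(names)))
    return GradientTable(
        pd.concat(frames), EnergyMetadata(temperature, unit)
    )


def make_unk(u, origins, states, names=("fep-lambda",), temperature=300.0,
             unit="kT"):
    """ReducedPotentialTable from a dense (N, K) array of potentials.

    ``origins[n]`` is the index (into *states*) of the window sample n
    was drawn from; *states* are scalars or tuples.
    """
    u = np.asarray(u, dtype=float)
    origins = np.asarray(origins)
    states_t = [s if isinstance(s, tuple) else (s,) for s in states]
    order = np.argsort(origins, kind="stable")
    u = u[order]
    origins = origins[order]
    time = np.empty(len(u))
    for k in range(len(states)):
        m = origins == k
        time[m] = np.arange(m.sum(), dtype=float)
    arrays = [time] + [
        np.array([states_t[o][c] for o in origins])
        for c in range(len(names))
    ]
    idx = pd.MultiIndex.from_arrays(arrays, names=["time", *names])
    frame = pd.DataFrame(u, index=idx)
    frame.columns = pd.Index(states_t, tupleize_cols=False)
    return ReducedPotentialTable(frame, EnergyMetadata(temperature, unit))


def harmonic_unk(rng, force_constants, n, states=None):
    """Gaussian samples under harmonic states u_k = K_k x²/2."""
    ks = np.asarray(force_constants, dtype=float)
    K = len(ks)
    if states is None:
        states = list(np.linspace(0.0, 1.0, K))
    xs = [rng.normal(0.0, 1.0 / np.sqrt(k), n) for k in ks]
    x = np.concatenate(xs)
    origins = np.repeat(np.arange(K), n)
    u = 0.5 * np.outer(x**2, ks)
    return make_unk(u, origins, states)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_dhdl():
    """Three windows with constant gradients 1.0 — Δf(0→1) = 1.0."""
    return make_dhdl(
        [np.full(10, 1.0), np.full(10, 1.0), np.full(10, 1.0)],
        [0.0, 0.5, 1.0],
    )


@pytest.fixture
def two_state_unk(rng):
    """Two harmonic states K = 1, 4: exact Δf = ½ ln 4."""
    return harmonic_unk(rng, [1.0, 4.0], 2000, states=[0.0, 1.0])
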