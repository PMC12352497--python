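"""Optional plot veneers over the numeric diagnostics.

Every figure here visualizes a table computed elsewhere (the tables are
the tested artifacts); matplotlib is imported lazily so the core
library works without it.  Install the ``alchest[plot]`` extra to use
this module.
"""

from __future__ import annotations

import numpy as np


def _pyplot():
    try:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting needs matplotlib; install the 'alchest[plot]' extra"
        ) from exc
    return plt


def plot_overlap_matrix(overlap, path) -> None:
    """Heatmap of the phase-space overlap matrix."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(overlap.O, vmin=0, vmax=1, cmap="viridis")
    ax.set_xlabel("state j")
    ax.set_ylabel("state i")
    ax.set_title("phase-space overlap  $O_{ij}$")
    fig.colorbar(im, ax=ax)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_convergence(series, path) -> None:
    """Forward/backward endpoint estimate vs fraction of data."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5.5, 4))
    frac = np.asarray(series.fractions)
    ax.errorbar(frac, series.forward_df, yerr=series.forward_err,
                marker="o", label="forward")
    ax.errorbar(frac, series.backward_df, yerr=series.backward_err,
                marker="s", label="backward")
    ax.set_xlabel("fraction of simulation time")
    ax.set_ylabel(r"$\Delta f$ (kT)")
    ax.legend()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_ti_integrand(ti_estimator, path) -> None:
    """Mean ⟨dH/dλ⟩ per window with SEM bars — the TI smoothness plot."""
    plt = _pyplot()
    means = ti_estimator.dhdl_means_
    sems = getattr(ti_estimator, "dhdl_sem_", None)
    lam = [v[0] if isinstance(v, tuple) else v for v in means.index]
    y = means.to_numpy(dtype=float).sum(axis=1)
    err = sems.to_numpy(dtype=float).sum(axis=1) if sems is not None else None
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.errorbar(lam, y, yerr=err, marker="o")
    ax.set_xlabel(r"$\lambda$")
    ax.set_ylabel(r"$\langle dH/d\lambda \rangle$ (kT)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
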