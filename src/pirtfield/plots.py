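"""Minimal diagnostic figures (fit scatter, fraction curve, mu histogram)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .annual import MuDistribution
from .pirt import PirtFit, maintenance_fraction, predict_rsb


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_fit(mu, r_sb, fits: list[PirtFit], path: str | Path) -> None:
    """Scatter of R_sb vs mu with the fitted model curve(s)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(mu, r_sb, "o", color="0.3", ms=4)
    grid = np.linspace(0, float(np.max(mu)), 200)
    for fit, style in zip(fits, ["--", "-"]):
        ax.plot(grid, predict_rsb(fit, grid), style, label=f"{fit.form} (rm={fit.rm:.2f})")
    ax.set_xlabel(r"$\mu$ (day$^{-1}$)")
    ax.set_ylabel(r"$R_{sb}$ (fmol O$_2$ day$^{-1}$ cell$^{-1}$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fraction_curve(fit: PirtFit, path: str | Path, mu_max: float = 0.28) -> None:
    """Maintenance fraction R_m/R_sb as a function of growth rate."""
    plt = _plt()
    grid = np.linspace(1e-4, mu_max, 300)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(grid, 100 * np.asarray(maintenance_fraction(fit, grid)), "-")
    ax.set_xlabel(r"$\mu$ (day$^{-1}$)")
    ax.set_ylabel(r"$R_m/R_{sb}$ (%)")
    ax.set_ylim(0, 100)
    ax.set_title(f"{fit.form} model")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_mu_histogram(dist: MuDistribution, path: str | Path) -> None:
    """Annual growth-rate histogram (bin fractions)."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 4))
    width = dist.bin_edges[1] - dist.bin_edges[0]
    ax.bar(dist.midpoints, dist.f_h, width=0.9 * width, color="0.5")
    ax.set_xlabel(r"$\mu$ (day$^{-1}$)")
    ax.set_ylabel("fraction of observations")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
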