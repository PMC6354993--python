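"""Diagnostic figures: singular values, eigenvalue planes, spectra, sweeps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .decomposition import ModeBasis

__all__ = [
    "plot_singular_values",
    "plot_eigenvalues",
    "plot_continuous_eigenvalues",
    "plot_spectrum",
    "plot_sweep",
]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_singular_values(basis: ModeBasis, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    s = basis.singular_values
    ax.semilogy(np.arange(1, len(s) + 1), s, "o-", ms=3)
    ax.set_xlabel("mode index")
    ax.set_ylabel(r"singular value $\sigma_i$")
    ax.set_title(f"{basis.method} singular values")
    return _save(fig, path)


def plot_eigenvalues(basis: ModeBasis, path: str | Path) -> Path:
    """Discrete eigenvalues λ relative to the unit circle."""
    if basis.eigenvalues is None:
        raise ValueError("basis has no eigenvalues (POD/PCA)")
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    t = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(t), np.sin(t), "b--", lw=1, label="unit circle")
    lam = basis.eigenvalues
    ax.scatter(lam.real, lam.imag, s=18, c="crimson")
    ax.set_xlabel(r"Re $\lambda$")
    ax.set_ylabel(r"Im $\lambda$")
    ax.set_aspect("equal")
    ax.set_title(f"{basis.method} eigenvalues")
    ax.legend(loc="upper right", fontsize=8)
    return _save(fig, path)


def plot_continuous_eigenvalues(basis: ModeBasis, path: str | Path) -> Path:
    """Transformed eigenvalues ω = log(λ)/(2π); Re ω < 0 means decay."""
    if basis.continuous_eigenvalues is None:
        raise ValueError("basis has no continuous eigenvalues")
    om = basis.continuous_eigenvalues
    finite = np.isfinite(om.real)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(om.real[finite], om.imag[finite], s=18, c="teal")
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel(r"Re $\omega$ (growth/decay)")
    ax.set_ylabel(r"Im $\omega$ (frequency)")
    ax.set_title(rf"{basis.method}: $\omega = \log(\lambda)/(2\pi)$")
    return _save(fig, path)


def plot_spectrum(basis: ModeBasis, path: str | Path) -> Path:
    """Mode-amplitude spectrum |b| against frequency |Im ω|."""
    if basis.amplitudes is None or basis.continuous_eigenvalues is None:
        raise ValueError("basis has no amplitude spectrum")
    freq = np.abs(basis.continuous_eigenvalues.imag)
    amp = np.abs(basis.amplitudes)
    finite = np.isfinite(freq)
    order = np.argsort(freq[finite])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.stem(freq[finite][order], amp[finite][order], basefmt=" ")
    for period in (3, 5, 9):
        ax.axvline(1.0 / period, color="gray", ls=":", lw=0.8)
    ax.set_xlabel(r"frequency $|\mathrm{Im}\,\omega|$")
    ax.set_ylabel("mode amplitude $|b|$")
    ax.set_title(f"{basis.method} spectrum (dotted: periods 3, 5, 9)")
    return _save(fig, path)


def plot_sweep(sweep: pd.DataFrame, path: str | Path) -> Path:
    """Mean CV accuracy against the number of retained modes, per method/classifier."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.8), sharey=True)
    for ax, clf in zip(axes, ("RF", "SVM")):
        sub = sweep[sweep["classifier"] == clf]
        for method, grp in sub.groupby("method"):
            grp = grp.sort_values("r")
            ax.errorbar(grp["r"], grp["mean_acc"], yerr=grp["sd"], marker="o",
                        ms=4, capsize=2, label=method)
        ax.set_xlabel("retained eigenmodes r")
        ax.set_title(clf)
    axes[0].set_ylabel("mean CV accuracy")
    axes[0].legend(fontsize=8)
    return _save(fig, path)
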