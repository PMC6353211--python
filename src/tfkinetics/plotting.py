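"""Diagnostic plots for the fitted models.

Matplotlib is imported lazily so headless pipelines that never plot do not pay
for a backend.
"""

from __future__ import annotations

import numpy as np

from .displacement import DiffusionFit, DiffusionMixtureModel, mixture_density
from .frap import FrapCurve, FrapFit
from .residence import ExpFitResult, SurvivalCurve
from .simulate import frap_model

__all__ = ["plot_survival_fit", "plot_frap_fit", "plot_displacement_fit"]


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_survival_fit(curve: SurvivalCurve, fit: ExpFitResult | None = None, ax=None):
    """Semilog survival curve with an optional exponential-fit overlay."""
    ax = _ax(ax)
    ax.semilogy(curve.times, curve.survival, ".", ms=3, label=f"data (n={curve.n_events})")
    if fit is not None:
        t = np.linspace(curve.times[0], curve.times[-1], 400)
        amp0 = curve.survival[0] / sum(
            f * np.exp(-curve.times[0] / tau) for f, tau in zip(fit.fractions, fit.lifetimes)
        )
        y = sum(amp0 * f * np.exp(-t / tau) for f, tau in zip(fit.fractions, fit.lifetimes))
        label = " + ".join(f"{f:.2f}·e^(-t/{tau:.2g}s)" for f, tau in
                           zip(fit.fractions, fit.lifetimes))
        ax.semilogy(t, y, "-", label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("survival probability")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_frap_fit(curve: FrapCurve, fit: FrapFit | None = None, ax=None):
    """Post-bleach recovery trace with an optional double-exponential overlay."""
    ax = _ax(ax)
    ax.plot(curve.times, curve.intensity, ".", ms=2, label="data")
    if fit is not None:
        t = np.linspace(0, curve.times[-1], 400)
        ax.plot(t, frap_model(t, fit.i1, fit.tau1, fit.i2, fit.tau2), "-",
                label=f"fit (t1/2 = {fit.t_half_global:.2g} s)")
        ax.axhline(fit.i1 + fit.i2, ls=":", lw=0.8, color="grey")
    ax.set_xlabel("time after bleach (s)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_displacement_fit(model: DiffusionMixtureModel, fit: DiffusionFit | None = None, ax=None):
    """Step-length histogram with the fitted mixture density per component."""
    ax = _ax(ax)
    ax.bar(model.centres, model.density, width=model.bin_width * 0.9,
           alpha=0.4, label="data")
    if fit is not None:
        r = np.linspace(0, model.centres[-1], 400)
        dt = model.ssd.dt
        ax.plot(r, mixture_density(r, fit.fractions, fit.diffusivities, dt),
                "-", label="mixture")
        for f, d in zip(fit.fractions, fit.diffusivities):
            ax.plot(r, mixture_density(r, [f], [d], dt), "--", lw=0.8,
                    label=f"f={f:.2f}, D={d:.2g}")
    ax.set_xlabel("single-step displacement (um)")
    ax.set_ylabel("probability density (1/um)")
    ax.legend(frameon=False, fontsize=8)
    return ax
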