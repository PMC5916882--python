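"""Basic diagnostic plots (optional; requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .dispersion import DispersionFit
from .fes import FreeEnergySurface
from .ratefit import DecaySeries, RateEstimate


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_decay(series: DecaySeries, fit: RateEstimate | None = None, ax=None):
    """Intensity decay with the fitted mono-exponential overlaid."""
    ax = _axes(ax)
    ax.errorbar(series.delays, series.intensities, yerr=series.sigma_exp,
                fmt="o", label="data")
    if fit is not None:
        t = np.linspace(series.delays[0], series.delays[-1], 200)
        ax.plot(t, fit.i0 * np.exp(-fit.rate * t),
                label=f"fit: R = {fit.rate:.3g} 1/s")
    ax.set_xlabel("delay (s)")
    ax.set_ylabel("intensity (a.u.)")
    ax.legend()
    return ax


def plot_dispersion(fit: DispersionFit, ax=None):
    """R1ρ dispersion profile with its Lorentzian fit."""
    ax = _axes(ax)
    p = fit.profile
    if p is not None:
        use = ~p.censored
        ax.errorbar(p.nu_sl[use], p.r1rho[use], yerr=p.sd[use], fmt="o")
    nu = np.linspace(1.0, 25.0, 200)
    ax.plot(nu, fit.model(nu),
            label=f"ΔRex = {fit.delta_rex:.2g} 1/s"
            + (" (exchange)" if fit.flagged else " (flat)"))
    ax.set_xlabel("spin-lock amplitude (kHz)")
    ax.set_ylabel("R1ρ (1/s)")
    ax.legend()
    return ax


def plot_fes(surface: FreeEnergySurface, ax=None):
    """2-D free-energy surface in kT (masked cells blank)."""
    if surface.free_energy.ndim != 2:
        raise ValueError("only 2-D surfaces can be drawn; marginalize first")
    ax = _axes(ax)
    x, y = surface.edges
    f = np.ma.masked_invalid(surface.free_energy)
    pcm = ax.pcolormesh(x, y, f.T, shading="auto")
    ax.figure.colorbar(pcm, ax=ax, label="free energy (kT)")
    ax.set_xlabel(surface.cv_names[0])
    ax.set_ylabel(surface.cv_names[1])
    return ax
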