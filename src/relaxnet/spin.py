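"""Closed-form amide ¹⁵N relaxation rates from the simple model-free spectral density.

The rates of an amide ¹⁵N nucleus are assumed to be dominated by the
dipolar coupling to its bonded ¹H and by its chemical shift anisotropy
(CSA).  Local motion is described by the Lipari–Szabo simple model-free
(SMF) spectral density, parameterised by an order parameter ``S²``
(amplitude of motion; 1 = rigid) and an effective correlation time
``τ_eff``.  These closed forms are the forward model for both the
synthetic-data generator and the model-free inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import constants as _const

__all__ = [
    "SpinSystem",
    "ModelFreeParams",
    "SpinLock",
    "dipolar_constant",
    "spectral_density",
    "r1_rate",
    "r1rho_rate",
]

#: ¹H gyromagnetic ratio (rad s⁻¹ T⁻¹), CODATA.
GAMMA_H = _const.value("proton gyromag. ratio")
#: ¹⁵N gyromagnetic ratio (rad s⁻¹ T⁻¹); negative sign is physical.
GAMMA_N = -2.71261804e7


@dataclass(frozen=True)
class SpinSystem:
    """Static field and spin-pair geometry defining the relaxation prefactors.

    Parameters
    ----------
    b0_mhz:
        Static field expressed as the ¹H Larmor frequency in MHz.
    r_nh:
        N–H bond length in Å.
    delta_sigma:
        ¹⁵N CSA in ppm; enters the rate expressions as the dimensionless
        fraction ``delta_sigma * 1e-6`` multiplying ωN.
    gamma_h, gamma_n:
        Gyromagnetic ratios in rad s⁻¹ T⁻¹.  γN < 0; spectral densities are
        even in ω so only magnitudes of frequency combinations matter.
    """

    b0_mhz: float = 800.0
    r_nh: float = 1.02
    delta_sigma: float = 170.0
    gamma_h: float = GAMMA_H
    gamma_n: float = GAMMA_N
    mu0: float = field(default=_const.mu_0, repr=False)
    hbar: float = field(default=_const.hbar, repr=False)

    def __post_init__(self) -> None:
        if self.b0_mhz <= 0:
            raise ValueError(f"b0_mhz must be positive, got {self.b0_mhz}")
        if self.r_nh <= 0:
            raise ValueError(f"r_nh must be positive, got {self.r_nh}")
        if self.delta_sigma < 0:
            raise ValueError(f"delta_sigma must be >= 0, got {self.delta_sigma}")

    @property
    def omega_h(self) -> float:
        """¹H Larmor frequency in rad/s (positive by convention)."""
        return 2.0 * np.pi * self.b0_mhz * 1e6

    @property
    def omega_n(self) -> float:
        """¹⁵N Larmor frequency in rad/s (signed; negative for ¹⁵N)."""
        return self.omega_h * self.gamma_n / self.gamma_h


@dataclass(frozen=True)
class ModelFreeParams:
    """Simple model-free parameters: order parameter and correlation time."""

    s2: float
    tau_eff: float  # seconds

    def __post_init__(self) -> None:
        if not 0.0 <= self.s2 <= 1.0:
            raise ValueError(f"s2 must lie in [0, 1], got {self.s2}")
        if self.tau_eff <= 0:
            raise ValueError(f"tau_eff must be positive, got {self.tau_eff}")


@dataclass(frozen=True)
class SpinLock:
    """Spin-lock RF field amplitude, stored in kHz."""

    nu_sl: float

    def __post_init__(self) -> None:
        if self.nu_sl <= 0:
            raise ValueError(f"nu_sl must be positive, got {self.nu_sl}")

    @property
    def omega_sl(self) -> float:
        """Spin-lock frequency in rad/s."""
        return 2.0 * np.pi * self.nu_sl * 1e3


def dipolar_constant(spin: SpinSystem) -> float:
    """Dipolar coupling constant d = μ0 ħ |γN| |γH| / (4π r_NH³) in rad/s."""
    r_m = spin.r_nh * 1e-10
    return (
        spin.mu0
        * spin.hbar
        * abs(spin.gamma_n)
        * abs(spin.gamma_h)
        / (4.0 * np.pi * r_m**3)
    )


def _j(omega, s2, tau):
    """SMF spectral density, vectorised over any broadcastable arguments."""
    wt = np.asarray(omega) * np.asarray(tau)
    return 0.4 * (1.0 - np.asarray(s2)) * np.asarray(tau) / (1.0 + wt * wt)


def spectral_density(omega: float, params: ModelFreeParams) -> float:
    """J(ω) = (2/5)(1−S²)τ / (1+(ωτ)²), in s/rad.

    Even in ω, and identical for every spin-interaction index in the SMF
    framework, so a single function serves all terms in the rate formulas.
    """
    return float(_j(omega, params.s2, params.tau_eff))


def _r1(spin: SpinSystem, s2, tau):
    """Vectorised R1; s2 and tau may be broadcastable arrays."""
    d = dipolar_constant(spin)
    wh, wn = spin.omega_h, spin.omega_n
    dsig = spin.delta_sigma * 1e-6
    dip = (d * d / 4.0) * (
        _j(wh - wn, s2, tau) + 3.0 * _j(wn, s2, tau) + 6.0 * _j(wh + wn, s2, tau)
    )
    csa = (wn * wn * dsig * dsig / 3.0) * _j(wn, s2, tau)
    return dip + csa


def _r1rho(spin: SpinSystem, s2, tau, omega_sl):
    """Vectorised on-resonance R1ρ; s2, tau, omega_sl broadcastable."""
    d = dipolar_constant(spin)
    wh, wn = spin.omega_h, spin.omega_n
    dsig = spin.delta_sigma * 1e-6
    dip = (d * d / 8.0) * (
        4.0 * _j(omega_sl, s2, tau)
        + _j(wh - wn, s2, tau)
        + 3.0 * _j(wn, s2, tau)
        + 6.0 * _j(wh, s2, tau)
        + 6.0 * _j(wh + wn, s2, tau)
    )
    csa = (wn * wn * dsig * dsig / 18.0) * (
        4.0 * _j(omega_sl, s2, tau) + 3.0 * _j(wn, s2, tau)
    )
    return dip + csa


def r1_rate(spin: SpinSystem, params: ModelFreeParams) -> float:
    """Longitudinal ¹⁵N relaxation rate R1 in s⁻¹.

    R1 = (d²/4)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + (ωN²Δσ²/3) J(ωN)
    with Δσ the unitless CSA fraction.
    """
    return float(_r1(spin, params.s2, params.tau_eff))


def r1rho_rate(spin: SpinSystem, params: ModelFreeParams, lock: SpinLock) -> float:
    """Rotating-frame ¹⁵N relaxation rate R1ρ under an on-resonance spin lock.

    R1ρ = (d²/8)[4J(ωSL) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
        + (ωN²Δσ²/18)[4J(ωSL) + 3J(ωN)]

    No MAS-rate or off-resonance corrections are applied; anisotropy of the
    overall motion is not modelled.
    """
    return float(_r1rho(spin, params.s2, params.tau_eff, lock.omega_sl))
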