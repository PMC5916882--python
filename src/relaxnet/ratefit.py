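"""Per-residue relaxation-rate extraction from intensity decay curves.

Intensity decay under both R1 and R1ρ experiments is treated as a
mono-exponential process ``I(t) = I0 exp(-R t)``.  The pair ``(I0, R)`` is
obtained by minimising the reduced chi-square

    χ² = (1/N) Σ_k (I_exp(t_k) − I0 e^{−R t_k})² / σ²

where σ is the experimental noise level (spectrum RMSD).  Uncertainties are
estimated by Monte-Carlo: synthetic datasets are produced by adding Gaussian
noise to the back-calculated curve, refit, and the error is the standard
deviation of the resulting rate ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .spin import SpinLock

__all__ = [
    "DecaySeries",
    "RateEstimate",
    "UnfittableError",
    "chi_square",
    "fit_decay",
    "monte_carlo_errors",
    "estimate_rate",
    "ExponentialDecayFitter",
]


class UnfittableError(ValueError):
    """Raised when a decay series carries no usable signal."""


@dataclass(frozen=True)
class DecaySeries:
    """One residue's intensity-vs-delay measurements for one experiment.

    ``delays`` are stored sorted and must be strictly increasing; duplicated
    delays should be averaged upstream (see :func:`relaxnet.io.read_intensity_table`).
    ``lock`` is mandatory for R1ρ series, where it records the spin-lock
    amplitude the decay was measured under.
    """

    residue_id: str
    experiment: str  # "R1" or "R1rho"
    delays: np.ndarray  # seconds
    intensities: np.ndarray
    sigma_exp: float
    lock: Optional[SpinLock] = None

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays, dtype=float)
        intens = np.asarray(self.intensities, dtype=float)
        if self.experiment not in ("R1", "R1rho"):
            raise ValueError(f"experiment must be 'R1' or 'R1rho', got {self.experiment!r}")
        if delays.shape != intens.shape or delays.ndim != 1:
            raise ValueError("delays and intensities must be 1-D arrays of equal length")
        if delays.size < 3:
            raise ValueError(f"need >= 3 points, got {delays.size}")
        if np.any(delays < 0):
            raise ValueError("delays must be non-negative")
        order = np.argsort(delays)
        delays, intens = delays[order], intens[order]
        if np.any(np.diff(delays) <= 0):
            raise ValueError("delays must be distinct")
        if not self.sigma_exp > 0:
            raise ValueError(f"sigma_exp must be positive, got {self.sigma_exp}")
        if self.experiment == "R1rho" and self.lock is None:
            raise ValueError("R1rho series requires a SpinLock")
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "intensities", intens)


@dataclass(frozen=True)
class RateEstimate:
    """Fitted mono-exponential rate with Monte-Carlo uncertainty."""

    rate: float  # s^-1
    i0: float
    rate_sd: float  # s^-1; 0 until Monte-Carlo is run
    chi2: float
    n_mc: int = 0
    seed: Optional[int] = None
    residue_id: str = ""
    experiment: str = ""


def chi_square(series: DecaySeries, i0: float, rate: float) -> float:
    """Reduced chi-square of a candidate (i0, rate) against the series."""
    calc = i0 * np.exp(-rate * series.delays)
    resid = series.intensities - calc
    return float(np.mean(resid * resid) / series.sigma_exp**2)


def _loglinear_rate(t: np.ndarray, intens: np.ndarray) -> np.ndarray:
    """Vectorised log-linear initial rate estimate; intens is (m, n)."""
    mask = intens > 0
    y = np.where(mask, np.log(np.where(mask, intens, 1.0)), 0.0)
    w = mask.astype(float)
    sw = w.sum(axis=1)
    swx = (w * t).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swxx = (w * t * t).sum(axis=1)
    swxy = (w * t * y).sum(axis=1)
    denom = swxx - swx * swx / np.maximum(sw, 1.0)
    num = swxy - swx * swy / np.maximum(sw, 1.0)
    ok = (sw >= 2) & (denom > 0)
    slope = np.where(ok, num / np.where(denom > 0, denom, 1.0), 0.0)
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    return np.where(ok, -slope, 1.0 / span)


def _chi2_many(rates: np.ndarray, t: np.ndarray, intens: np.ndarray, sigma) -> tuple:
    """Profiled chi-square for each row: i0 is optimal in closed form."""
    expo = np.clip(-rates[..., None] * t, -700.0, 700.0)
    u = np.exp(expo)
    i0 = (intens * u).sum(axis=-1) / (u * u).sum(axis=-1)
    resid = intens - i0[..., None] * u
    chi2 = (resid * resid).sum(axis=-1) / (t.size * np.asarray(sigma) ** 2)
    return chi2, i0


def _fit_exponential_many(
    t: np.ndarray, intens: np.ndarray, sigma, n_refine: int = 16, n_scan: int = 33
) -> tuple:
    """Minimise the profiled chi-square over the rate for each row of `intens`.

    Adaptive scan-and-shrink: a symmetric grid around the current best rate
    is evaluated, the bracket re-centred on the grid argmin and shrunk (or
    expanded when the argmin sits on the boundary).  Fully vectorised over
    rows; converges to ~1e-12 relative precision on clean data.
    """
    t = np.asarray(t, dtype=float)
    intens = np.atleast_2d(np.asarray(intens, dtype=float))
    m = intens.shape[0]
    center = _loglinear_rate(t, intens)
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    half = np.maximum(np.abs(center), 1.0 / span)
    offsets = np.linspace(-1.0, 1.0, n_scan)
    for _ in range(n_refine + 12):  # extra iterations absorb bracket expansions
        grid = center[:, None] + half[:, None] * offsets[None, :]
        chi2, _ = _chi2_many(grid, t, intens[:, None, :], np.ones(m)[:, None])
        best = np.argmin(chi2, axis=1)
        center = grid[np.arange(m), best]
        on_edge = (best == 0) | (best == n_scan - 1)
        half = np.where(on_edge, half * 2.0, half * (2.0 / (n_scan - 1)) * 2.0)
        if not np.any(on_edge) and np.all(half <= 1e-13 * (1.0 + np.abs(center))):
            break
    chi2, i0 = _chi2_many(center, t, intens, sigma)
    return center, i0, chi2


def fit_decay(series: DecaySeries) -> RateEstimate:
    """Fit (i0, rate) to a decay series by chi-square minimisation.

    Initialisation is a log-linear regression on the positive intensities;
    ``i0`` is profiled out in closed form at every trial rate, so the search
    is one-dimensional and deterministic.  A negative best-fit rate is
    reported as-is with a warning (never clamped, so Monte-Carlo rate
    distributions stay symmetric).
    """
    intens = series.intensities
    if np.all(intens <= 0):
        raise UnfittableError(
            f"residue {series.residue_id}: all intensities non-positive"
        )
    rate, i0, chi2 = _fit_exponential_many(
        series.delays, intens[None, :], series.sigma_exp
    )
    rate_f = float(rate[0])
    if rate_f < 0:
        warnings.warn(
            f"residue {series.residue_id} ({series.experiment}): fitted rate is "
            f"negative ({rate_f:.4g} s^-1)",
            stacklevel=2,
        )
    return RateEstimate(
        rate=rate_f,
        i0=float(i0[0]),
        rate_sd=0.0,
        chi2=float(chi2[0]),
        residue_id=series.residue_id,
        experiment=series.experiment,
    )


def monte_carlo_errors(
    series: DecaySeries, fit: RateEstimate, n: int = 1000, seed: int = 0
) -> float:
    """Monte-Carlo standard deviation of the fitted rate.

    ``n`` synthetic datasets are built from the back-calculated curve of
    ``fit`` plus Gaussian noise of width ``sigma_exp``, each refit with the
    same objective; the returned error is the standard deviation of the
    refit rates.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 Monte-Carlo replicates, got {n}")
    rng = np.random.default_rng(seed)
    t = series.delays
    curve = fit.i0 * np.exp(-fit.rate * t)
    synth = curve[None, :] + rng.normal(0.0, series.sigma_exp, size=(n, t.size))
    rates, _, _ = _fit_exponential_many(t, synth, series.sigma_exp)
    return float(np.std(rates, ddof=1))


def estimate_rate(
    series: DecaySeries, n_mc: int = 1000, seed: int = 0
) -> RateEstimate:
    """Convenience wrapper: fit the decay, then attach Monte-Carlo errors."""
    base = fit_decay(series)
    sd = monte_carlo_errors(series, base, n=n_mc, seed=seed)
    return RateEstimate(
        rate=base.rate,
        i0=base.i0,
        rate_sd=sd,
        chi2=base.chi2,
        n_mc=n_mc,
        seed=seed,
        residue_id=series.residue_id,
        experiment=series.experiment,
    )


class ExponentialDecayFitter(BaseEstimator):
    """Mono-exponential decay regressor with chi-square objective.

    scikit-learn style: ``fit(t, y)`` estimates ``i0_`` and ``rate_`` and,
    when ``n_mc > 0``, the Monte-Carlo uncertainty ``rate_sd_``.

    Parameters
    ----------
    sigma:
        Noise level of the intensities (spectrum RMSD), same units as ``y``.
    n_mc:
        Number of Monte-Carlo replicates for the rate uncertainty
        (0 disables the error estimate).
    seed:
        Seed for the Monte-Carlo noise generator.
    """

    def __init__(self, sigma: float = 1.0, n_mc: int = 1000, seed: int = 0):
        self.sigma = sigma
        self.n_mc = n_mc
        self.seed = seed

    def fit(self, t: Sequence[float], y: Sequence[float]) -> "ExponentialDecayFitter":
        t = np.asarray(t, dtype=float).ravel()
        series = DecaySeries(
            residue_id="-", experiment="R1", delays=t,
            intensities=np.asarray(y, dtype=float), sigma_exp=self.sigma,
        )
        if self.n_mc > 0:
            est = estimate_rate(series, n_mc=self.n_mc, seed=self.seed)
        else:
            est = fit_decay(series)
        self.rate_ = est.rate
        self.i0_ = est.i0
        self.rate_sd_ = est.rate_sd
        self.chi2_ = est.chi2
        return self

    def predict(self, t: Sequence[float]) -> np.ndarray:
        t = np.asarray(t, dtype=float).ravel()
        return self.i0_ * np.exp(-self.rate_ * t)
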