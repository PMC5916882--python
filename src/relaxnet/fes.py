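"""Weighted-histogram free-energy surfaces over collective-variable samples.

Samples from an enhanced-sampling simulation arrive with per-sample
statistical weights (the reweighting itself is upstream and out of scope).
The CV space is divided into a homogeneous grid; the free energy of each
cell is F = −ln(Σ w in cell / Σ w) in kT units, shifted so the sampled
minimum is zero.  Lower-dimensional surfaces are obtained by integrating
out CVs in probability space (i.e. histogramming only the kept dimensions),
and substate populations by summing cell weights over a user-declared
partition of the grid into basins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "CVSamples",
    "FreeEnergySurface",
    "UnlabeledCellsError",
    "weighted_fes",
    "marginalize",
    "basin_populations",
    "WeightedHistogramFES",
    "KT_TO_KJ_278K",
]

#: kT in kJ/mol at 278 K (reporting-layer conversion; internals stay in kT).
KT_TO_KJ_278K = 2.311


class UnlabeledCellsError(ValueError):
    """Raised when sampled grid cells fall outside every declared basin."""


@dataclass(frozen=True)
class CVSamples:
    """Collective-variable samples with statistical weights.

    values: (n_samples, n_cv); weights: (n_samples,), non-negative with a
    positive sum.  CV columns are opaque reaction coordinates (e.g.
    antiparallel-β content, side-chain rotamer state).
    """

    values: np.ndarray
    weights: np.ndarray
    cv_names: Tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if v.ndim != 2 or w.shape != (v.shape[0],):
            raise ValueError("values must be (n, d) with one weight per sample")
        if not np.all(np.isfinite(v)) or not np.all(np.isfinite(w)):
            raise ValueError("values and weights must be finite")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be >= 0 with positive sum")
        names = tuple(self.cv_names)
        if len(names) != v.shape[1]:
            raise ValueError("need one cv name per column")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "cv_names", names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def select(self, keep: Sequence[str]) -> "CVSamples":
        idx = [self.cv_names.index(k) for k in keep]
        return CVSamples(self.values[:, idx], self.weights, tuple(keep))


@dataclass(frozen=True)
class FreeEnergySurface:
    """Free energy per grid cell in kT units.

    ``free_energy`` holds NaN on unsampled cells; ``sampled`` is the
    corresponding boolean mask.  The minimum over sampled cells is 0.
    """

    edges: Tuple[np.ndarray, ...]
    free_energy: np.ndarray
    sampled: np.ndarray
    cv_names: Tuple[str, ...]

    def probability(self) -> np.ndarray:
        """exp(−F) normalised over sampled cells (sums to 1)."""
        p = np.where(self.sampled, np.exp(-np.nan_to_num(self.free_energy)), 0.0)
        return p / p.sum()

    @property
    def min_location(self) -> Tuple[float, ...]:
        idx = np.unravel_index(
            np.nanargmin(np.where(self.sampled, self.free_energy, np.nan)),
            self.free_energy.shape,
        )
        return tuple(
            0.5 * (e[i] + e[i + 1]) for e, i in zip(self.edges, idx)
        )


def weighted_fes(
    samples: CVSamples,
    bins,
    range: Optional[Sequence[Tuple[float, float]]] = None,
) -> FreeEnergySurface:
    """Weighted-histogram free energy on a homogeneous CV grid.

    F_cell = −ln(weight share of cell), shifted so the sampled minimum is 0;
    unsampled cells are masked (NaN), never reported as 0.
    """
    if samples.n_samples == 0:
        raise ValueError("no samples")
    bins_arr = np.broadcast_to(np.asarray(bins, dtype=int), (samples.values.shape[1],))
    if np.any(bins_arr < 2):
        raise ValueError("need >= 2 bins per retained dimension")
    hist, edges = np.histogramdd(
        samples.values, bins=list(bins_arr), range=range, weights=samples.weights
    )
    total = hist.sum()
    sampled = hist > 0
    with np.errstate(divide="ignore"):
        f = -np.log(np.where(sampled, hist / total, 1.0))
    f = f - f[sampled].min()
    f = np.where(sampled, f, np.nan)
    return FreeEnergySurface(
        edges=tuple(np.asarray(e) for e in edges),
        free_energy=f,
        sampled=sampled,
        cv_names=samples.cv_names,
    )


def marginalize(
    samples: CVSamples,
    keep: Sequence[str],
    bins,
    range: Optional[Sequence[Tuple[float, float]]] = None,
) -> FreeEnergySurface:
    """Lower-dimensional surface with the non-kept CVs integrated out.

    Integration happens in probability space: the kept dimensions are
    re-histogrammed directly, which is exactly the sum of cell
    probabilities over the dropped axes.
    """
    keep = list(keep)
    if not keep:
        raise ValueError("keep must name at least one CV")
    return weighted_fes(samples.select(keep), bins, range=range)


def basin_populations(
    samples: CVSamples,
    basins: Mapping[str, Mapping[str, Tuple[float, float]]],
    bins=32,
) -> Dict[str, float]:
    """Statistical weight share of user-declared rectangular basins.

    Each basin is a dict mapping CV names to (low, high) intervals; CVs not
    mentioned are unbounded, so basins may be declared on any subset of the
    CVs.  Cell membership is decided at the cell centre (first matching
    basin wins).  Sampled cells covered by no basin raise
    :class:`UnlabeledCellsError` listing the offending cell centres.
    """
    if not basins:
        raise ValueError("at least one basin must be declared")
    bins_arr = np.broadcast_to(np.asarray(bins, dtype=int), (samples.values.shape[1],))
    hist, edges = np.histogramdd(
        samples.values, bins=list(bins_arr), weights=samples.weights
    )
    centers = [0.5 * (e[:-1] + e[1:]) for e in edges]
    mesh = np.meshgrid(*centers, indexing="ij")
    labels = np.full(hist.shape, -1, dtype=int)
    names = list(basins)
    for b_idx in reversed(range(len(names))):  # earlier basins overwrite later
        rect = basins[names[b_idx]]
        unknown = set(rect) - set(samples.cv_names)
        if unknown:
            raise ValueError(f"basin {names[b_idx]!r} references unknown CVs {unknown}")
        inside = np.ones(hist.shape, dtype=bool)
        for cv, (lo, hi) in rect.items():
            ax = samples.cv_names.index(cv)
            inside &= (mesh[ax] >= lo) & (mesh[ax] <= hi)
        labels[inside] = b_idx
    stray = (hist > 0) & (labels < 0)
    if np.any(stray):
        pts = np.argwhere(stray)[:10]
        locs = [tuple(float(centers[d][i]) for d, i in enumerate(p)) for p in pts]
        raise UnlabeledCellsError(
            f"{int(stray.sum())} sampled cells outside all basins, e.g. {locs}"
        )
    total = hist.sum()
    return {
        name: float(hist[labels == b_idx].sum() / total)
        for b_idx, name in enumerate(names)
    }


class WeightedHistogramFES(BaseEstimator):
    """scikit-learn style transformer from weighted CV samples to a surface.

    ``fit(X, sample_weight=...)`` builds the grid and exposes
    ``free_energy_``, ``edges_`` and ``sampled_``.
    """

    def __init__(self, bins=32, cv_names: Optional[Sequence[str]] = None):
        self.bins = bins
        self.cv_names = cv_names

    def fit(self, X, y=None, sample_weight=None) -> "WeightedHistogramFES":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        names = (
            tuple(self.cv_names)
            if self.cv_names is not None
            else tuple(f"cv{i}" for i in range(X.shape[1]))
        )
        w = (
            np.ones(X.shape[0])
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        surface = weighted_fes(CVSamples(X, w, names), self.bins)
        self.surface_ = surface
        self.free_energy_ = surface.free_energy
        self.edges_ = surface.edges
        self.sampled_ = surface.sampled
        return self

    def transform(self, X=None) -> np.ndarray:
        return self.free_energy_
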