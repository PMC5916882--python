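"""Ensemble interaction-energy matrices, difference networks and charge scans.

For a conformational ensemble with per-atom partial charges and
Lennard-Jones parameters, the nonbonded interaction energy of every residue
pair (Coulomb + 12-6 LJ, distance cutoff) is averaged over the ensemble,
giving an interaction matrix.  Subtracting the matrix of a reference
(wild-type) ensemble from a perturbed (mutant) one and thresholding at the
largest gap in the distribution of the differences yields a sparse network
of interactions strengthened or weakened by the perturbation.  A related
scan recomputes the total nonbonded energy after removing or inverting the
side-chain charges of single residues, a cheap predictor of the stability
change caused by charge-altering mutations that can be correlated with
measured melting temperatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy import constants as _const
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr, spearmanr

__all__ = [
    "COULOMB_KJ_A",
    "BACKBONE_ATOMS",
    "ChargedEnsemble",
    "InteractionMatrix",
    "EnergyNetwork",
    "MutationSpec",
    "NoGapError",
    "pair_energy",
    "ensemble_matrix",
    "find_gap",
    "difference_network",
    "charge_scan",
    "correlate_with_tm",
    "CorrelationResult",
]

#: Coulomb prefactor e²·N_A / (4π ε0) in kJ/mol · Å / e².
COULOMB_KJ_A = _const.e**2 * _const.N_A / (4.0 * np.pi * _const.epsilon_0 * 1e-10) / 1000.0

#: Atom names treated as backbone (never touched by side-chain charge edits).
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "HA2", "HA3", "H1", "H2", "H3"}
)

MIN_DISTANCE = 0.1  # Å; closer atom pairs indicate a broken structure


class NoGapError(ValueError):
    """Raised when the energy-difference distribution has no usable gap."""


@dataclass
class ChargedEnsemble:
    """Multi-model structure with per-atom charges and LJ parameters.

    coords: (n_models, n_atoms, 3) in Å.  ``res_index`` is 1-based and
    contiguous.  ``weights`` are per-model statistical weights, normalised
    to sum to 1 on construction.
    """

    coords: np.ndarray
    charge: np.ndarray  # e
    lj_sigma: np.ndarray  # Å
    lj_epsilon: np.ndarray  # kJ/mol
    res_index: np.ndarray  # 1-based
    res_name: np.ndarray
    atom_name: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        for name in ("charge", "lj_sigma", "lj_epsilon"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n_atoms,):
                raise ValueError(f"{name} must have length {n_atoms}")
            setattr(self, name, arr)
        self.res_index = np.asarray(self.res_index, dtype=int)
        self.res_name = np.asarray(self.res_name, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        if self.res_index.shape != (n_atoms,):
            raise ValueError("res_index must have one entry per atom")
        uniq = np.unique(self.res_index)
        if uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
            raise ValueError("residue indices must be contiguous starting at 1")
        if self.weights is None:
            self.weights = np.full(self.n_models, 1.0 / self.n_models)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.n_models,) or np.any(w < 0):
                raise ValueError("weights must be non-negative, one per model")
            total = w.sum()
            if total <= 0:
                raise ValueError("model weights sum to zero")
            self.weights = w / total

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.res_index.max())

    def with_charges(self, charge: np.ndarray) -> "ChargedEnsemble":
        return ChargedEnsemble(
            coords=self.coords,
            charge=np.asarray(charge, dtype=float),
            lj_sigma=self.lj_sigma,
            lj_epsilon=self.lj_epsilon,
            res_index=self.res_index,
            res_name=self.res_name,
            atom_name=self.atom_name,
            weights=self.weights,
        )


@dataclass(frozen=True)
class InteractionMatrix:
    """Ensemble-averaged residue-pair nonbonded energies (kJ/mol).

    Symmetric; the diagonal and sequence neighbours (|i−j| ≤ 1) are zeroed,
    since their "nonbonded" energy is dominated by fixed covalent geometry.
    """

    matrix: np.ndarray
    cutoff: float  # Å
    dielectric: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("matrix must be square")
        object.__setattr__(self, "matrix", m)

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class EnergyNetwork:
    """Gap-thresholded difference network between two interaction matrices.

    Each edge carries the energy difference ΔE = E_perturbed − E_reference;
    ``strengthened`` means the interaction became more favourable (ΔE < 0).
    """

    edges: Tuple[Tuple[int, int, float, str], ...]
    gap_threshold: float

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, j, de, sign in self.edges:
            g.add_edge(i, j, delta_e=de, sign=sign)
        return g

    @property
    def edge_set(self) -> set:
        return {(i, j) for i, j, _, _ in self.edges}


@dataclass(frozen=True)
class MutationSpec:
    """A single-residue charge edit: remove or invert side-chain charges."""

    residue: int  # 1-based
    edit: str  # "remove_side_chain_charge" | "invert_side_chain_charge"

    def __post_init__(self) -> None:
        if self.edit not in ("remove_side_chain_charge", "invert_side_chain_charge"):
            raise ValueError(f"unknown edit {self.edit!r}")


def _atom_pair_energy(
    d: np.ndarray,
    q: np.ndarray,
    sig: np.ndarray,
    eps: np.ndarray,
    mask: np.ndarray,
    dielectric: float,
) -> np.ndarray:
    """Per-atom-pair nonbonded energy on masked entries of distance matrix d."""
    if np.any(d[mask] < MIN_DISTANCE):
        raise ValueError(
            f"overlapping atoms: interatomic distance below {MIN_DISTANCE} Å"
        )
    safe = np.where(mask, d, 1.0)
    coul = COULOMB_KJ_A * np.outer(q, q) / (dielectric * safe)
    sij = 0.5 * (sig[:, None] + sig[None, :])
    eij = np.sqrt(np.outer(eps, eps))
    sr6 = (sij / safe) ** 6
    lj = 4.0 * eij * (sr6 * sr6 - sr6)
    return np.where(mask, coul + lj, 0.0)


def pair_energy(
    ens: ChargedEnsemble,
    model: int,
    i: int,
    j: int,
    cutoff: float = 10.0,
    dielectric: float = 1.0,
) -> float:
    """Nonbonded energy between residues i and j (1-based) in one model.

    Sum over atom pairs within ``cutoff`` of Coulomb (with relative
    dielectric) plus 12-6 Lennard-Jones with Lorentz–Berthelot combining.
    Sequence neighbours and self pairs are rejected.
    """
    if abs(i - j) <= 1:
        raise ValueError("pair energies are defined only for |i - j| > 1")
    sel_i = ens.res_index == i
    sel_j = ens.res_index == j
    if not sel_i.any() or not sel_j.any():
        raise ValueError("residue index out of range")
    xi = ens.coords[model][sel_i]
    xj = ens.coords[model][sel_j]
    d = cdist(xi, xj)
    mask = d < cutoff
    if not mask.any():
        return 0.0
    if np.any(d[mask] < MIN_DISTANCE):
        raise ValueError(
            f"overlapping atoms between residues {i} and {j} in model {model}"
        )
    qi, qj = ens.charge[sel_i], ens.charge[sel_j]
    si, sj = ens.lj_sigma[sel_i], ens.lj_sigma[sel_j]
    ei, ej = ens.lj_epsilon[sel_i], ens.lj_epsilon[sel_j]
    safe = np.where(mask, d, 1.0)
    coul = COULOMB_KJ_A * np.outer(qi, qj) / (dielectric * safe)
    sij = 0.5 * (si[:, None] + sj[None, :])
    eij = np.sqrt(np.outer(ei, ej))
    sr6 = (sij / safe) ** 6
    lj = 4.0 * eij * (sr6 * sr6 - sr6)
    return float(np.where(mask, coul + lj, 0.0).sum())


def ensemble_matrix(
    ens: ChargedEnsemble, cutoff: float = 10.0, dielectric: float = 1.0
) -> InteractionMatrix:
    """Weight-averaged residue-pair energy matrix over the ensemble."""
    n_res = ens.n_residues
    ri = ens.res_index
    pair_ok = np.abs(ri[:, None] - ri[None, :]) > 1
    out = np.zeros((n_res, n_res))
    for m in range(ens.n_models):
        x = ens.coords[m]
        d = cdist(x, x)
        mask = pair_ok & (d < cutoff)
        e_atom = _atom_pair_energy(
            d, ens.charge, ens.lj_sigma, ens.lj_epsilon, mask, dielectric
        )
        acc = np.zeros((n_res, n_res))
        np.add.at(acc, (ri[:, None] - 1, ri[None, :] - 1), e_atom)
        out += ens.weights[m] * acc
    # the full atom-pair matrix puts E_ij on both (i,j) and (j,i);
    # halve and re-symmetrise so each entry is the physical pair energy
    out *= 0.5
    out = out + out.T
    np.fill_diagonal(out, 0.0)
    return InteractionMatrix(matrix=out, cutoff=cutoff, dielectric=dielectric)


def find_gap(values: Sequence[float], decile: float = 0.1) -> float:
    """Threshold at the largest gap in the upper tail of |ΔE| order statistics.

    Values are sorted by decreasing magnitude; candidate split points keep
    the top k elements for k = 1 … max(2, ⌈decile·n⌉) and the split with the
    largest gap between consecutive order statistics wins.  Ties break
    toward the larger threshold (sparser network).  Returns the midpoint of
    the winning gap.
    """
    v = np.abs(np.asarray(values, dtype=float))
    v = np.sort(v[v > 0])[::-1]
    if v.size < 2:
        raise NoGapError("need at least 2 nonzero values to locate a gap")
    kmax = min(max(2, int(np.ceil(decile * v.size))), v.size - 1)
    gaps = v[:kmax] - v[1 : kmax + 1]
    if np.max(gaps) <= 0:
        raise NoGapError("all magnitudes equal; no gap in the distribution")
    k = int(np.argmax(gaps))  # first occurrence = larger threshold on ties
    return float(0.5 * (v[k] + v[k + 1]))


def difference_network(
    mat_ref: InteractionMatrix, mat_per: InteractionMatrix, decile: float = 0.1
) -> EnergyNetwork:
    """Network of residue pairs whose interaction energy changes beyond the gap.

    ΔE = perturbed − reference, evaluated on all non-neighbour pairs; edges
    are the pairs with |ΔE| above the :func:`find_gap` threshold.  Identical
    matrices (or a gap-free distribution) yield an empty network with a
    warning rather than an error.
    """
    if mat_ref.matrix.shape != mat_per.matrix.shape:
        raise ValueError("interaction matrices have mismatched residue counts")
    delta = mat_per.matrix - mat_ref.matrix
    iu = np.triu_indices_from(delta, k=2)
    vals = delta[iu]
    try:
        thr = find_gap(vals[vals != 0], decile=decile)
    except NoGapError as exc:
        warnings.warn(f"no energy gap found ({exc}); returning empty network")
        return EnergyNetwork(edges=(), gap_threshold=np.inf)
    edges = []
    for i, j, de in zip(iu[0], iu[1], vals):
        if abs(de) >= thr:
            sign = "strengthened" if de < 0 else "weakened"
            edges.append((int(i) + 1, int(j) + 1, float(de), sign))
    return EnergyNetwork(edges=tuple(edges), gap_threshold=thr)


def _side_chain_mask(ens: ChargedEnsemble, residue: int) -> np.ndarray:
    sel = ens.res_index == residue
    if not sel.any():
        raise ValueError(f"residue {residue} not in ensemble")
    resname = str(ens.res_name[sel][0]).upper()
    side = sel & np.array([a not in BACKBONE_ATOMS for a in ens.atom_name])
    if resname == "GLY" or not side.any():
        raise ValueError(
            f"residue {residue} ({resname}) has no side-chain atoms to edit"
        )
    return side


def _coulomb_kernel(
    ens: ChargedEnsemble, cutoff: float, dielectric: float
) -> np.ndarray:
    """Ensemble-averaged Coulomb kernel A with E_coul(q) = ½ qᵀ A q."""
    ri = ens.res_index
    pair_ok = np.abs(ri[:, None] - ri[None, :]) > 1
    a = np.zeros((ens.n_atoms, ens.n_atoms))
    for m in range(ens.n_models):
        d = cdist(ens.coords[m], ens.coords[m])
        mask = pair_ok & (d < cutoff)
        if np.any(d[mask] < MIN_DISTANCE):
            raise ValueError(f"overlapping atoms in model {m}")
        safe = np.where(mask, d, 1.0)
        a += ens.weights[m] * np.where(mask, COULOMB_KJ_A / (dielectric * safe), 0.0)
    return a


def charge_scan(
    ens: ChargedEnsemble,
    muts: Sequence[MutationSpec],
    cutoff: float = 10.0,
    dielectric: float = 1.0,
) -> List[float]:
    """Total-energy change from single-residue side-chain charge edits.

    For each mutation the total ensemble-averaged nonbonded energy is
    recomputed with the edited charges; only Coulomb terms change, so the
    result is ΔE = ½ (q'ᵀ A q' − qᵀ A q) with A the ensemble-averaged
    Coulomb kernel.  Returns one ΔE (kJ/mol) per mutation.
    """
    a = _coulomb_kernel(ens, cutoff, dielectric)
    q0 = ens.charge
    e0 = 0.5 * q0 @ a @ q0
    out = []
    for mut in muts:
        side = _side_chain_mask(ens, mut.residue)
        q = q0.copy()
        if mut.edit == "remove_side_chain_charge":
            q[side] = 0.0
        else:
            q[side] = -q[side]
        out.append(float(0.5 * q @ a @ q - e0))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    pearson: float
    spearman: float
    n: int


def correlate_with_tm(
    delta_e: Sequence[float], tm: Sequence[float]
) -> CorrelationResult:
    """Pearson and Spearman correlation between predicted ΔE and melting Tm."""
    de = np.asarray(delta_e, dtype=float)
    t = np.asarray(tm, dtype=float)
    if de.shape != t.shape or de.ndim != 1:
        raise ValueError("delta_e and tm must be paired 1-D sequences")
    if de.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(de) == 0 or np.std(t) == 0:
        raise ValueError("zero variance: correlation undefined")
    return CorrelationResult(
        pearson=float(pearsonr(de, t).statistic),
        spearman=float(spearmanr(de, t).statistic),
        n=int(de.size),
    )
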