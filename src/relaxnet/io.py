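"""File formats: TSV tables, multi-MODEL PQR ensembles and PDB fallback.

Conventions used throughout: coordinates in Å, residues 1-based, energies
in kJ/mol, rates in s⁻¹, free energies in kT; TSV (never CSV) for all
tables.  Output tables carry ``#``-prefixed header lines stating units and
the configuration hash.

PQR files are PDB-shaped but whitespace-delimited, with per-atom charge (e)
and radius (Å) in place of occupancy/B-factor; multi-model ensembles use
MODEL/ENDMDL records.  There is no installed reader for multi-model PQR, so
the (trivially line-oriented) format is parsed here; PDB files are read
through biotite and joined with a companion per-atom charge table.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import biotite.structure.io.pdb as pdb_io

from .dispersion import DispersionProfile
from .energetics import ChargedEnsemble
from .ratefit import DecaySeries
from .spin import SpinLock

__all__ = [
    "read_intensity_table",
    "write_intensity_table",
    "read_dispersion_table",
    "write_dispersion_table",
    "read_pqr_ensemble",
    "write_pqr",
    "read_pdb_ensemble",
    "ELEMENT_EPSILON",
]

INTENSITY_COLUMNS = ["residue", "experiment", "delay", "intensity", "sigma"]

#: Default LJ well depths (kJ/mol) by element, applied when the input format
#: (PQR) carries radii but no epsilon.
ELEMENT_EPSILON = {"H": 0.066, "C": 0.36, "N": 0.71, "O": 0.88, "S": 1.05}
DEFAULT_EPSILON = 0.30


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def _numeric(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    bad_lines: List[int] = []
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        # +2: 1-based line numbers plus the header row
        bad_lines.extend((df.index[bad] + 2).tolist())
        df[c] = coerced
    if bad_lines:
        raise ValueError(
            f"{path}: non-numeric fields on line(s) {sorted(set(bad_lines))}"
        )
    return df


def read_intensity_table(path) -> List[DecaySeries]:
    """Read a per-residue intensity decay TSV into DecaySeries objects.

    Required columns: residue, experiment (R1|R1rho), delay (s), intensity,
    sigma.  R1rho rows additionally need a ``nu_sl`` column (spin-lock kHz).
    Duplicated (residue, experiment, delay) rows are averaged with a
    warning; malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _check_columns(df, INTENSITY_COLUMNS, path)
    num_cols = ["delay", "intensity", "sigma"] + (
        ["nu_sl"] if "nu_sl" in df.columns else []
    )
    df = _numeric(df, num_cols, path)
    series = []
    for (res, exp), grp in df.groupby(["residue", "experiment"], sort=True):
        if grp["delay"].duplicated().any():
            warnings.warn(
                f"{path}: duplicated delays for {res}/{exp}; averaging intensities"
            )
            agg = {"intensity": "mean", "sigma": "first"}
            if "nu_sl" in grp.columns:
                agg["nu_sl"] = "first"
            grp = grp.groupby("delay", as_index=False).agg(agg)
        lock = None
        if exp == "R1rho":
            if "nu_sl" not in grp.columns or grp["nu_sl"].isna().all():
                raise ValueError(f"{path}: R1rho rows for {res} lack a nu_sl column")
            lock = SpinLock(float(grp["nu_sl"].iloc[0]))
        series.append(
            DecaySeries(
                residue_id=str(res),
                experiment=str(exp),
                delays=grp["delay"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                sigma_exp=float(grp["sigma"].iloc[0]),
                lock=lock,
            )
        )
    return series


def write_intensity_table(series: Sequence[DecaySeries], path, header: str = "") -> None:
    rows = []
    for s in series:
        for t, inten in zip(s.delays, s.intensities):
            rows.append(
                {
                    "residue": s.residue_id,
                    "experiment": s.experiment,
                    "delay": t,
                    "intensity": inten,
                    "sigma": s.sigma_exp,
                    "nu_sl": s.lock.nu_sl if s.lock is not None else "",
                }
            )
    _write_tsv(pd.DataFrame(rows), path, header)


def read_dispersion_table(path) -> List[DispersionProfile]:
    """Read R1ρ-vs-spin-lock TSV (columns residue, nu_sl, r1rho, sd[, censored])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    _check_columns(df, ["residue", "nu_sl", "r1rho", "sd"], path)
    df = _numeric(df, ["nu_sl", "r1rho", "sd"], path)
    profiles = []
    for res, grp in df.groupby("residue", sort=True):
        cen = (
            grp["censored"].astype(str).str.lower().isin(("1", "true", "yes")).to_numpy()
            if "censored" in grp.columns
            else None
        )
        profiles.append(
            DispersionProfile(
                residue_id=str(res),
                nu_sl=grp["nu_sl"].to_numpy(),
                r1rho=grp["r1rho"].to_numpy(),
                sd=grp["sd"].to_numpy(),
                censored=cen,
            )
        )
    return profiles


def write_dispersion_table(profiles: Sequence[DispersionProfile], path, header: str = "") -> None:
    rows = []
    for p in profiles:
        for nu, r, sd, cen in zip(p.nu_sl, p.r1rho, p.sd, p.censored):
            rows.append(
                {"residue": p.residue_id, "nu_sl": nu, "r1rho": r, "sd": sd,
                 "censored": int(bool(cen))}
            )
    _write_tsv(pd.DataFrame(rows), path, header)


def _write_tsv(df: pd.DataFrame, path, header: str = "") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in filter(None, header.split("\n")):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_pqr(ens: ChargedEnsemble, path) -> None:
    """Write a multi-MODEL PQR file (whitespace-delimited, charge+radius).

    The LJ radius column stores σ/2·2^{1/6} (the van-der-Waals radius
    corresponding to the atom's σ), so a round trip through
    :func:`read_pqr_ensemble` preserves σ.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rvdw = ens.lj_sigma / 2.0 * 2.0 ** (1.0 / 6.0)
    with open(path, "w") as fh:
        for m in range(ens.n_models):
            fh.write(f"MODEL     {m + 1}\n")
            for a in range(ens.n_atoms):
                x, y, z = ens.coords[m, a]
                fh.write(
                    f"ATOM  {a + 1:>5d} {str(ens.atom_name[a]):<4s} "
                    f"{str(ens.res_name[a]):<4s} {int(ens.res_index[a]):>5d}    "
                    f"{x:8.3f} {y:8.3f} {z:8.3f} "
                    f"{ens.charge[a]:8.4f} {rvdw[a]:7.4f}\n"
                )
            fh.write("ENDMDL\n")


def _epsilon_for(atom_name: str) -> float:
    element = atom_name.strip()[:1].upper()
    return ELEMENT_EPSILON.get(element, DEFAULT_EPSILON)


def read_pqr_ensemble(path, weights: Optional[Sequence[float]] = None) -> ChargedEnsemble:
    """Read a multi-MODEL PQR file into a ChargedEnsemble.

    Radii are interpreted as van-der-Waals radii and converted to LJ σ;
    well depths default by element (:data:`ELEMENT_EPSILON`).  All models
    must share atom count and order.  ``weights`` is an optional per-model
    weight vector (e.g. from a sidecar TSV).
    """
    models: List[List[List[float]]] = []
    meta: List[tuple] = []
    current: List[List[float]] = []
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line.split()
            if not rec:
                continue
            if rec[0] == "MODEL":
                current, in_model = [], True
            elif rec[0] == "ENDMDL":
                models.append(current)
                in_model = False
            elif rec[0] in ("ATOM", "HETATM"):
                if not in_model and not models:
                    in_model = True  # single-model file without MODEL records
                name, resn, resi = rec[2], rec[3], int(rec[4])
                x, y, z, q, r = map(float, rec[5:10])
                current.append([x, y, z, q, r])
                if len(models) == 0:
                    meta.append((name, resn, resi))
    if current and (not models or models[-1] is not current):
        models.append(current)
    if not models:
        raise ValueError(f"{path}: no ATOM records found")
    n_atoms = len(models[0])
    for k, mdl in enumerate(models):
        if len(mdl) != n_atoms:
            raise ValueError(
                f"{path}: model {k + 1} has {len(mdl)} atoms, expected {n_atoms}"
            )
    arr = np.asarray(models, dtype=float)
    atom_name = np.array([m[0] for m in meta], dtype=object)
    res_name = np.array([m[1] for m in meta], dtype=object)
    res_index = np.array([m[2] for m in meta], dtype=int)
    rvdw = arr[0, :, 4]
    return ChargedEnsemble(
        coords=arr[:, :, :3],
        charge=arr[0, :, 3],
        lj_sigma=2.0 * rvdw / 2.0 ** (1.0 / 6.0),
        lj_epsilon=np.array([_epsilon_for(a) for a in atom_name]),
        res_index=res_index,
        res_name=res_name,
        atom_name=atom_name,
        weights=None if weights is None else np.asarray(weights, dtype=float),
    )


def read_pdb_ensemble(
    pdb_path, charge_table_path, weights: Optional[Sequence[float]] = None
) -> ChargedEnsemble:
    """Read a multi-MODEL PDB plus a per-atom charge/radius TSV.

    The companion table must have columns atom (serial, 1-based, matching
    file order), charge and radius; the result is equivalent to reading the
    same ensemble from PQR.
    """
    pdbf = pdb_io.PDBFile.read(str(pdb_path))
    stack = pdbf.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    table = pd.read_csv(charge_table_path, sep="\t", comment="#")
    _check_columns(table, ["atom", "charge", "radius"], charge_table_path)
    table = table.sort_values("atom")
    if len(table) != coords.shape[1]:
        raise ValueError(
            f"{charge_table_path}: {len(table)} rows for {coords.shape[1]} atoms"
        )
    first = stack[0] if coords.shape[0] > 1 or stack.coord.ndim == 3 else stack
    atom_name = np.array(list(first.atom_name), dtype=object)
    res_name = np.array(list(first.res_name), dtype=object)
    res_id = np.asarray(first.res_id, dtype=int)
    # re-map residue ids to a contiguous 1-based range
    uniq = np.unique(res_id)
    remap = {int(r): k + 1 for k, r in enumerate(uniq)}
    res_index = np.array([remap[int(r)] for r in res_id], dtype=int)
    rvdw = table["radius"].to_numpy(dtype=float)
    return ChargedEnsemble(
        coords=coords,
        charge=table["charge"].to_numpy(dtype=float),
        lj_sigma=2.0 * rvdw / 2.0 ** (1.0 / 6.0),
        lj_epsilon=np.array([_epsilon_for(a) for a in atom_name]),
        res_index=res_index,
        res_name=res_name,
        atom_name=atom_name,
        weights=None if weights is None else np.asarray(weights, dtype=float),
    )


def read_model_weights(path) -> np.ndarray:
    """Read a per-model weight sidecar TSV (columns model, weight)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    _check_columns(df, ["model", "weight"], path)
    df = df.sort_values("model")
    return df["weight"].to_numpy(dtype=float)
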