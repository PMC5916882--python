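"""Pipeline orchestration: configuration, stages and deterministic outputs.

Stages (each independently switchable):

* ``simulate``   — write synthetic inputs + ground truth into the run dir
* ``rates``      — intensity tables → per-residue R1/R1ρ with MC errors
* ``modelfree``  — rate pairs → (S², τ_eff); dispersion-flagged residues
                   are excluded from model-free interpretation
* ``dispersion`` — R1ρ(ν_SL) profiles → Lorentzian fits and ΔRex
* ``energetics`` — PQR ensembles → interaction matrices, difference network
* ``fes``        — weighted CV samples → free-energy surface + populations

All outputs are TSV/JSON, deterministic given (config, seed); every table
header embeds the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .dispersion import fit_lorentzian
from .energetics import MutationSpec, difference_network, ensemble_matrix
from .fes import basin_populations, marginalize, weighted_fes
from .modelfree import fit_model_free
from .ratefit import estimate_rate
from .spin import SpinLock, SpinSystem
from .synthetic import (
    R1_DELAYS_S,
    R1RHO_DELAYS_S,
    SPINLOCK_GRID_KHZ,
    gen_charged_ensemble,
    gen_cv_samples,
    gen_relaxation_dataset,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("relaxnet")

ALL_STAGES = ("simulate", "rates", "dispersion", "modelfree", "energetics", "fes")


@dataclass
class RunConfig:
    """Validated run configuration, serialisable to/from YAML."""

    outdir: str = "relaxnet_run"
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES
    field_mhz: float = 800.0
    lock_khz: float = 20.0
    spinlock_grid_khz: Tuple[float, ...] = SPINLOCK_GRID_KHZ
    delays_r1_s: Tuple[float, ...] = R1_DELAYS_S
    delays_r1rho_s: Tuple[float, ...] = R1RHO_DELAYS_S
    n_mc: int = 1000
    n_residues: int = 40
    noise_frac: float = 0.02
    cutoff: float = 10.0
    dielectric: float = 1.0
    gap_decile: float = 0.1
    fes_bins: int = 40
    fes_keep: Tuple[str, ...] = ("anti_beta", "ab")
    basins: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {
            "major": {"anti_beta": (0.7, 10.0)},
            "minor": {"anti_beta": (-10.0, 0.7)},
        }
    )

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.n_mc < 2:
            raise ValueError("n_mc must be >= 2")
        if self.field_mhz <= 0 or self.lock_khz <= 0 or self.cutoff <= 0:
            raise ValueError("field_mhz, lock_khz and cutoff must be positive")
        if not 0 < self.gap_decile <= 1:
            raise ValueError("gap_decile must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(asdict(self))), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientifically meaningful settings (output location excluded)."""
        d = asdict(self)
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def spin_system(self) -> SpinSystem:
        return SpinSystem(b0_mhz=self.field_mhz)


def _header(config: RunConfig, units: str) -> str:
    return f"config_hash={config.config_hash}\n{units}"


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run the configured stages; returns a summary dict (also written as JSON).

    Any stage failure aborts the run with a stage-tagged error message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    summary: Dict[str, object] = {"config_hash": config.config_hash, "stages": {}}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            result = _STAGE_FUNCS[stage](config, outdir)
        except Exception as exc:  # noqa: BLE001 - re-tag with stage name
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        summary["stages"][stage] = result
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    spin = config.spin_system()
    decays, profiles, truth = gen_relaxation_dataset(
        n_residues=config.n_residues,
        spin=spin,
        delays_r1=config.delays_r1_s,
        delays_r1rho=config.delays_r1rho_s,
        locks=config.spinlock_grid_khz,
        measurement_lock_khz=config.lock_khz,
        noise_frac=config.noise_frac,
        seed=config.seed,
    )
    hdr = _header(config, "delay in s, intensity arbitrary, sigma same units")
    rio.write_intensity_table(decays, outdir / "intensities.tsv", hdr)
    rio.write_dispersion_table(
        profiles, outdir / "dispersion_input.tsv",
        _header(config, "nu_sl in kHz, r1rho and sd in s^-1"),
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
    ref, mut, mutation = gen_charged_ensemble(seed=config.seed)
    rio.write_pqr(ref, outdir / "ensemble_ref.pqr")
    rio.write_pqr(mut, outdir / "ensemble_mut.pqr")
    samples = gen_cv_samples(n=50_000, seed=config.seed)
    df = pd.DataFrame(samples.values, columns=list(samples.cv_names))
    df["weight"] = samples.weights
    rio._write_tsv(df, outdir / "cv_samples.tsv", _header(config, "CVs unitless"))
    return {
        "n_residues": config.n_residues,
        "mutation": f"{mutation.residue}:{mutation.edit}",
        "n_cv_samples": samples.n_samples,
    }


def _stage_rates(config: RunConfig, outdir: Path) -> dict:
    series = rio.read_intensity_table(outdir / "intensities.tsv")
    rows = []
    for idx, s in enumerate(series):
        child_seed = int(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(idx,)).generate_state(1)[0]
            % (2**31)
        )
        est = estimate_rate(s, n_mc=config.n_mc, seed=child_seed)
        rows.append(
            {
                "residue": s.residue_id,
                "experiment": s.experiment,
                "rate": est.rate,
                "rate_sd": est.rate_sd,
                "i0": est.i0,
                "chi2": est.chi2,
                "nu_sl": s.lock.nu_sl if s.lock else "",
            }
        )
    df = pd.DataFrame(rows)
    rio._write_tsv(df, outdir / "rates.tsv", _header(config, "rate and rate_sd in s^-1"))
    return {"n_series": len(series)}


def _stage_dispersion(config: RunConfig, outdir: Path) -> dict:
    profiles = rio.read_dispersion_table(outdir / "dispersion_input.tsv")
    rows = []
    for p in profiles:
        f = fit_lorentzian(p)
        rows.append(
            {
                "residue": p.residue_id,
                "r_inf": f.r_inf,
                "amp": f.amp,
                "nu_half": f.nu_half,
                "delta_rex": f.delta_rex,
                "flagged": int(f.flagged),
                "chi2": f.chi2,
                "chi2_flat": f.chi2_flat,
            }
        )
    df = pd.DataFrame(rows)
    rio._write_tsv(
        df, outdir / "dispersion.tsv",
        _header(config, "rates in s^-1, nu_half in kHz"),
    )
    return {"n_profiles": len(profiles), "n_flagged": int(df["flagged"].sum())}


def _stage_modelfree(config: RunConfig, outdir: Path) -> dict:
    rates = pd.read_csv(outdir / "rates.tsv", sep="\t", comment="#")
    flagged: set = set()
    disp_path = outdir / "dispersion.tsv"
    if disp_path.exists():
        disp = pd.read_csv(disp_path, sep="\t", comment="#")
        flagged = set(disp.loc[disp["flagged"] == 1, "residue"].astype(str))
    spin = config.spin_system()
    lock = SpinLock(config.lock_khz)
    rows = []
    from .ratefit import RateEstimate

    for res_idx, (res, grp) in enumerate(rates.groupby("residue", sort=True)):
        r1 = grp[grp["experiment"] == "R1"]
        r2 = grp[grp["experiment"] == "R1rho"]
        if r1.empty or r2.empty:
            continue
        e1 = RateEstimate(
            rate=float(r1["rate"].iloc[0]), i0=float(r1["i0"].iloc[0]),
            rate_sd=float(r1["rate_sd"].iloc[0]), chi2=0.0, residue_id=str(res),
        )
        e2 = RateEstimate(
            rate=float(r2["rate"].iloc[0]), i0=float(r2["i0"].iloc[0]),
            rate_sd=float(r2["rate_sd"].iloc[0]), chi2=0.0, residue_id=str(res),
        )
        child_seed = int(
            np.random.SeedSequence(
                entropy=config.seed, spawn_key=(1, res_idx)
            ).generate_state(1)[0] % (2**31)
        )
        mf = fit_model_free(e1, e2, spin, lock, n_mc=config.n_mc, seed=child_seed)
        excluded = str(res) in flagged
        rows.append(
            {
                "residue": str(res),
                "s2": mf.params.s2,
                "s2_sd": mf.s2_sd,
                "tau_ns": mf.params.tau_eff * 1e9,
                "tau_sd_ns": mf.tau_sd * 1e9,
                "chi2": mf.chi2,
                "quality_flag": mf.quality_flag,
                "dispersion_excluded": int(excluded),
            }
        )
    df = pd.DataFrame(rows)
    rio._write_tsv(
        df, outdir / "modelfree.tsv",
        _header(config, "tau in ns; dispersion_excluded marks exchange-affected residues"),
    )
    return {
        "n_residues": len(df),
        "n_excluded_by_dispersion": int(df["dispersion_excluded"].sum()) if len(df) else 0,
    }


def _stage_energetics(config: RunConfig, outdir: Path) -> dict:
    ref = rio.read_pqr_ensemble(outdir / "ensemble_ref.pqr")
    mut = rio.read_pqr_ensemble(outdir / "ensemble_mut.pqr")
    m_ref = ensemble_matrix(ref, cutoff=config.cutoff, dielectric=config.dielectric)
    m_mut = ensemble_matrix(mut, cutoff=config.cutoff, dielectric=config.dielectric)
    net = difference_network(m_ref, m_mut, decile=config.gap_decile)
    rows = [
        {"res_i": i, "res_j": j, "delta_e": de, "sign": sign}
        for i, j, de, sign in net.edges
    ]
    rio._write_tsv(
        pd.DataFrame(rows, columns=["res_i", "res_j", "delta_e", "sign"]),
        outdir / "network_edges.tsv",
        _header(config, f"delta_e in kJ/mol; gap_threshold={net.gap_threshold:.6g}"),
    )
    try:
        import networkx as nx

        nx.write_graphml(net.to_networkx(), outdir / "network.graphml")
    except Exception:  # pragma: no cover - GraphML export is best-effort
        pass
    return {"n_edges": len(net.edges), "gap_threshold": net.gap_threshold}


def _stage_fes(config: RunConfig, outdir: Path) -> dict:
    df = pd.read_csv(outdir / "cv_samples.tsv", sep="\t", comment="#")
    cv_names = tuple(c for c in df.columns if c != "weight")
    from .fes import CVSamples

    samples = CVSamples(
        df[list(cv_names)].to_numpy(), df["weight"].to_numpy(), cv_names
    )
    surf = marginalize(samples, keep=list(config.fes_keep), bins=config.fes_bins)
    idx = np.argwhere(np.ones(surf.free_energy.shape, dtype=bool))
    centers = [0.5 * (e[:-1] + e[1:]) for e in surf.edges]
    rows = {
        config.fes_keep[d]: [float(centers[d][i[d]]) for i in idx]
        for d in range(len(config.fes_keep))
    }
    fvals = [surf.free_energy[tuple(i)] for i in idx]
    out = pd.DataFrame(rows)
    out["free_energy_kt"] = ["%.8g" % f if np.isfinite(f) else "nan" for f in fvals]
    rio._write_tsv(out, outdir / "fes.tsv", _header(config, "free energy in kT"))
    pops = basin_populations(samples, config.basins, bins=config.fes_bins)
    rio._write_tsv(
        pd.DataFrame(
            [{"basin": k, "population": v} for k, v in sorted(pops.items())]
        ),
        outdir / "populations.tsv",
        _header(config, "population = statistical weight share"),
    )
    return {"populations": pops}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rates": _stage_rates,
    "dispersion": _stage_dispersion,
    "modelfree": _stage_modelfree,
    "energetics": _stage_energetics,
    "fes": _stage_fes,
}
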