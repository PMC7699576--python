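"""End-to-end orchestration of the DDI analysis stages.

A single JSON config describes which stages run and with what inputs;
stages missing an input path fall back to the seeded synthetic generators
so the whole pipeline is runnable with no external data.  Every stage is a
pure function of (inputs, config, seed); the run manifest records the
config hash and per-output checksums so deterministic reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from fibriddi import depth, dft, druggability, energetics, mwc, structure, synth
from fibriddi import thermo as th
from fibriddi import transport as tr

STAGE_ORDER = [
    "validate",
    "druggability",
    "transport",
    "occupancy",
    "depth",
    "energetics",
    "dftrank",
    "thermo",
]


class ValidateCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pdb_path: str | None = None  # default: synthetic E-region stand-in


class DruggabilityCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pockets_csv: str | None = None
    cutoff: float = Field(druggability.DRUGGABLE_CUTOFF_DEFAULT, gt=0)


class TransportCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    profiles_csv: str | None = None
    trajectories_csv: str | None = None
    min_segment_length: float = Field(0.5, gt=0)
    exponent_n: int = Field(2, ge=1)


class OccupancyCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k_r_a: list[float] = [1.0, 2.0]
    k_r_b: list[float] = [1.5, 3.0]
    c: float = Field(0.1, gt=0, le=1)
    l_iso: float = Field(1.0, ge=0)
    max_dose: float = Field(10.0, gt=0)
    n_grid: int = Field(21, ge=2)


class DepthCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chain_count: int = Field(6, ge=1)
    chain_length: int = Field(20, ge=4)
    drop_lo: float = Field(1.0, ge=0)
    drop_hi: float = Field(2.0, ge=0)


class EnergeticsCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bin_width: float = Field(0.5, gt=0)
    pose_count: int = Field(100, ge=1)


class DftRankCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    configurations_csv: str | None = None  # default: packaged dimer table
    threshold_ev: float = Field(dft.NONCOVALENT_THRESHOLD_EV, gt=0)


class ThermoCfg(BaseModel):
    model_config = ConfigDict(extra="forbid")
    series_csv: str | None = None
    beta_true: float = -0.8
    cmc1: float = Field(10.0, gt=0)
    cmc2: float = Field(2.0, gt=0)
    alpha1: float = Field(0.5, gt=0, lt=1)
    noise_rel: float = Field(0.001, ge=0)
    temperature: float = Field(310.0, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    out_dir: str = "results/run"
    seed: int = 0
    validate_stage: ValidateCfg | None = Field(None, alias="validate")
    druggability: DruggabilityCfg | None = None
    transport: TransportCfg | None = None
    occupancy: OccupancyCfg | None = None
    depth: DepthCfg | None = None
    energetics: EnergeticsCfg | None = None
    dftrank: DftRankCfg | None = None
    thermo: ThermoCfg | None = None

    def enabled_stages(self) -> list[str]:
        alias = {"validate": "validate_stage"}
        return [
            s for s in STAGE_ORDER if getattr(self, alias.get(s, s)) is not None
        ]


def validate_config(path: str) -> RunConfig:
    """Parse and validate a JSON run config; raises with the full list of
    violations on schema errors."""
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot parse config {path!r}: {exc}") from exc
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ValueError(f"invalid config: {msgs}") from exc


# ----------------------------------------------------------- stage bodies


def _stage_validate(cfg: ValidateCfg, seed: int, out: Path) -> list[Path]:
    if cfg.pdb_path:
        s = structure.read_structure(cfg.pdb_path)
    else:
        s = synth.gen_synthetic_eregion(seed)
    structure.write_rama_report(s, out / "ramachandran.tsv")
    import importlib.resources as resources

    sites = json.loads(
        resources.files("fibriddi.data").joinpath("binding_sites.json").read_text()
    )
    rows = []
    for site in ("site1", "site2", "site3"):
        pct = structure.site_flexibility_report(
            s, [(c, n) for c, n in sites[site]]
        )
        rows.append({"site": site, "pct_favored_or_allowed": pct})
    pd.DataFrame(rows).to_csv(out / "site_flexibility.tsv", sep="\t", index=False)
    return [out / "ramachandran.tsv", out / "site_flexibility.tsv"]


def _stage_druggability(cfg: DruggabilityCfg, seed: int, out: Path) -> list[Path]:
    if cfg.pockets_csv:
        pockets = druggability.load_pockets_csv(cfg.pockets_csv)
    else:
        # demo descriptor set spanning druggable and undruggable pockets
        pockets = [
            druggability.PocketDescriptor("site1", a_nonpolar=450.0, s_max=4000.0),
            druggability.PocketDescriptor("site2", a_nonpolar=300.0, s_max=4000.0),
            druggability.PocketDescriptor("site3", a_nonpolar=217.0, s_max=4000.0),
            druggability.PocketDescriptor("worst", a_nonpolar=44.0, s_max=4000.0),
        ]
    table = druggability.ranking_table(pockets, cfg.cutoff)
    table.to_csv(out / "druggability.tsv", sep="\t", index=False)
    return [out / "druggability.tsv"]


def _stage_transport(cfg: TransportCfg, seed: int, out: Path) -> list[Path]:
    if cfg.profiles_csv:
        profiles = tr.load_tunnel_profiles_csv(cfg.profiles_csv)
    else:
        profiles = [synth.gen_tunnel_profile(seed)]
    rows = [
        {
            "site_id": p.site_id,
            "tunnel_id": p.tunnel_id,
            "cost": tr.pathway_cost(p),
            "throughput": tr.throughput(p),
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(out / "throughput.tsv", sep="\t", index=False)
    if cfg.trajectories_csv:
        trajs = tr.load_trajectories_csv(cfg.trajectories_csv)
        a, b = trajs[0], trajs[1]
    else:
        a, b, _ = synth.gen_trajectory_pair(seed)
    segs = tr.detect_ddi_segments(a, b, cfg.min_segment_length)
    pd.DataFrame(
        [
            {
                "start": s.start,
                "end": s.end,
                "mean_dG_A": s.mean_dg_a,
                "mean_dG_B": s.mean_dg_b,
            }
            for s in segs
        ]
    ).to_csv(out / "ddi_segments.tsv", sep="\t", index=False)
    return [out / "throughput.tsv", out / "ddi_segments.tsv"]


def _stage_occupancy(cfg: OccupancyCfg, seed: int, out: Path) -> list[Path]:
    model = mwc.MWCSiteModel(
        k_r_a=cfg.k_r_a,
        k_r_b=cfg.k_r_b,
        c_a=[cfg.c] * len(cfg.k_r_a),
        c_b=[cfg.c] * len(cfg.k_r_b),
        l_iso=cfg.l_iso,
    )
    grid = np.linspace(0.0, cfg.max_dose, cfg.n_grid)
    doses = [mwc.LigandDose(a, a) for a in grid]
    mwc.occupancy_curve(model, doses).to_csv(
        out / "occupancy.tsv", sep="\t", index=False
    )
    return [out / "occupancy.tsv"]


def _stage_depth(cfg: DepthCfg, seed: int, out: Path) -> list[Path]:
    before, after, truth = synth.gen_depth_chains(
        seed,
        chain_count=cfg.chain_count,
        chain_length=cfg.chain_length,
        depth_drop=(cfg.drop_lo, cfg.drop_hi),
    )
    prof_b, _ = depth.residue_depth(before, "unbound")
    prof_a, _ = depth.residue_depth(after, "ligand-bound")
    dd, summary = depth.depth_perturbation(prof_b, prof_a)
    depth.profile_table(prof_b).to_csv(out / "depth_unbound.tsv", sep="\t", index=False)
    depth.profile_table(prof_a).to_csv(out / "depth_bound.tsv", sep="\t", index=False)
    rows = [{"chain": k[0], "pos": k[1], "dD": v} for k, v in sorted(dd.items())]
    rows.append({"chain": "ALL", "pos": 0, "dD": summary["mean"]})
    pd.DataFrame(rows).to_csv(out / "depth_perturbation.tsv", sep="\t", index=False)
    relevance = pd.DataFrame(
        [
            {"site": "site1", "chains": 6, "relevance": depth.chain_relevance(6)},
            {"site": "site2", "chains": 3, "relevance": depth.chain_relevance(3)},
            {"site": "site3", "chains": 3, "relevance": depth.chain_relevance(3)},
        ]
    )
    relevance.to_csv(out / "chain_relevance.tsv", sep="\t", index=False)
    return [
        out / "depth_unbound.tsv",
        out / "depth_bound.tsv",
        out / "depth_perturbation.tsv",
        out / "chain_relevance.tsv",
    ]


def _stage_energetics(cfg: EnergeticsCfg, seed: int, out: Path) -> list[Path]:
    hot = synth.gen_pose_ensemble(seed, "hot", cfg.pose_count)
    cold = synth.gen_pose_ensemble(seed + 1, "cold", cfg.pose_count)
    energetics.k_occurrence_histogram(hot, cfg.bin_width).to_csv(
        out / "k_occurrences_hot.tsv", sep="\t", index=False
    )
    energetics.k_occurrence_histogram(cold, cfg.bin_width).to_csv(
        out / "k_occurrences_cold.tsv", sep="\t", index=False
    )
    return [out / "k_occurrences_hot.tsv", out / "k_occurrences_cold.tsv"]


def _stage_dftrank(cfg: DftRankCfg, seed: int, out: Path) -> list[Path]:
    records = dft.load_configurations_csv(cfg.configurations_csv)
    dft.ranking_table(records).to_csv(out / "dft_ranking.tsv", sep="\t", index=False)
    return [out / "dft_ranking.tsv"]


def _stage_thermo(cfg: ThermoCfg, seed: int, out: Path) -> list[Path]:
    if cfg.series_csv:
        df = pd.read_csv(cfg.series_csv)
        series = th.UltrasoundSeries(
            temperature=float(df.T_K.iloc[0]),
            alpha1=float(df.alpha1.iloc[0]),
            molality=df.m_molkg.to_numpy(),
            density=df.rho_gcm3.to_numpy(),
            velocity=df.u_ms.to_numpy(),
            rho0=synth.WATER_RHO0,
            ks0=synth.WATER_KS0,
        )
        cmc1, cmc2 = cfg.cmc1, cfg.cmc2
    else:
        series, truth = synth.gen_ultrasound_series(
            seed,
            beta_true=cfg.beta_true,
            cmc1=cfg.cmc1,
            cmc2=cfg.cmc2,
            alpha1=cfg.alpha1,
            noise_rel=cfg.noise_rel,
        )
        cmc1, cmc2 = truth.cmc1, truth.cmc2
    cac = th.detect_cac(series)
    result = th.mixed_aggregation_analysis(cmc1, cmc2, cac, series.alpha1)
    ks = th.adiabatic_compressibility(series.density, series.velocity)
    pd.DataFrame(
        [
            {
                "cac": cac,
                "X1": result.x1,
                "beta_kBT": result.beta_kbt,
                "beta_kcal_mol": th.kbt_to_kcal(result.beta_kbt, cfg.temperature),
                "kS_min_Pa": float(np.min(ks)),
                "kS_max_Pa": float(np.max(ks)),
            }
        ]
    ).to_csv(out / "thermo.tsv", sep="\t", index=False)
    return [out / "thermo.tsv"]


_STAGE_FN: dict[str, Callable] = {
    "validate": _stage_validate,
    "druggability": _stage_druggability,
    "transport": _stage_transport,
    "occupancy": _stage_occupancy,
    "depth": _stage_depth,
    "energetics": _stage_energetics,
    "dftrank": _stage_dftrank,
    "thermo": _stage_thermo,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the run manifest (also written to ``manifest.json`` in the
    output directory).  A stage failure stops all downstream stages and is
    recorded with its stage name; the manifest's ``ok`` flag is False in
    that case.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = config.model_dump_json(by_alias=True)
    manifest: dict = {
        "tool_version": __import__("fibriddi").__version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "ok": True,
    }
    alias = {"validate": "validate_stage"}
    for stage in config.enabled_stages():
        cfg = getattr(config, alias.get(stage, stage))
        t0 = time.time()
        try:
            outputs = _STAGE_FN[stage](cfg, config.seed, out)
        except Exception as exc:
            manifest["stages"][stage] = {"error": f"{type(exc).__name__}: {exc}"}
            manifest["ok"] = False
            break
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
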