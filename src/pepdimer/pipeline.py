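"""Config-driven orchestration: simulate, analyze, report from one YAML file.

Every run writes a resolved copy of its configuration next to the outputs
and stamps the summary JSON with the seed and a hash of the resolved
config, so any scenario is bit-reproducible from the summary alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import census as census_mod
from . import msthermo, synthetic, trajectory

logger = logging.getLogger(__name__)


class VtesiBlock(BaseModel):
    breakpoint_temperature: float = 293.0
    dH_low: float = -26.4
    dH_high: float = -71.1
    mTdS_ref_high: float = 53.6
    reference_temperature: float = 293.0
    temperature_start: float = 278.0
    temperature_stop: float = 358.0
    temperature_step: float = 5.0
    monomer_intensity: float = 1000.0
    tmao_concentration: float = Field(5e-4, gt=0)
    replicates: int = Field(3, ge=1)
    cv: float = Field(0.0, ge=0)
    reaction: Literal["dimerization", "tmao_binding"] = "dimerization"
    breakpoint_mode: Literal["auto", "fixed"] = "auto"
    fixed_breakpoint: Optional[float] = None

    @model_validator(mode="after")
    def _check(self):
        if self.breakpoint_mode == "fixed" and self.fixed_breakpoint is None:
            raise ValueError("fixed_breakpoint required when breakpoint_mode=fixed")
        return self


class PotentialBlock(BaseModel):
    form: Literal["flat", "harmonic", "double_well", "tabulated"] = "double_well"
    params: dict = Field(
        default_factory=lambda: {"well_1": 1.5, "well_2": 3.5, "barrier": 5.0}
    )
    bounds: tuple[float, float] = (0.8, 4.2)


class TrajectoryBlock(BaseModel):
    input_csv: Optional[str] = None
    potential: PotentialBlock = Field(default_factory=PotentialBlock)
    temperature: float = Field(..., gt=0)
    dt: float = Field(0.001, gt=0)
    n_steps: int = Field(200_000, ge=1)
    diffusion_coefficient: float = Field(1.0, gt=0)
    n_bins: int = Field(40, ge=2)
    min_count: int = Field(10, ge=1)
    n_boot: int = Field(50, ge=2)
    block_length: int = Field(100, ge=1)
    dimer_threshold: float = 2.0
    monomer_threshold: float = 3.5

    @model_validator(mode="after")
    def _check(self):
        if self.dimer_threshold >= self.monomer_threshold:
            raise ValueError("dimer_threshold must be below monomer_threshold")
        return self


class SpeciesEntry(BaseModel):
    sequence: str
    order: int = Field(1, ge=1)
    charge: int = Field(1, ge=1)
    amide: bool = True
    adduct_mass: float = 0.0
    abundance: float = Field(0.0, ge=0)


class CensusBlock(BaseModel):
    species: list[SpeciesEntry]
    peak_fwhm: float = Field(0.5, gt=0)
    mz_low: float = 600.0
    mz_high: float = 2200.0
    tolerance: float = Field(0.25, gt=0)
    noise_floor: float = Field(0.0, ge=0)
    max_order: int = Field(3, ge=1)
    degree_definition: Literal["mass_fraction", "signal_fraction"] = "mass_fraction"


class PipelineConfig(BaseModel):
    scenario: Literal["vtesi_thermo", "trajectory", "census", "full"]
    seed: int = 0
    out_dir: str = "pipeline_out"
    vtesi: Optional[VtesiBlock] = None
    trajectory: Optional[TrajectoryBlock] = None
    census: Optional[CensusBlock] = None

    @model_validator(mode="after")
    def _scenario_blocks(self):
        needs = {
            "vtesi_thermo": ["vtesi"],
            "trajectory": ["trajectory"],
            "census": ["census"],
            "full": ["vtesi", "trajectory", "census"],
        }[self.scenario]
        missing = [name for name in needs if getattr(self, name) is None]
        if missing:
            raise ValueError(
                f"scenario {self.scenario!r} requires config block(s): {missing}"
            )
        return self


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a YAML config, collecting all errors."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        return None, [f"unparseable YAML: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]
    try:
        return PipelineConfig.model_validate(raw), []
    except ValidationError as exc:
        if "scenario" in {e["loc"][0] if e["loc"] else "" for e in exc.errors()}:
            allowed = "vtesi_thermo, trajectory, census, full"
            return None, [
                f"{'.'.join(map(str, e['loc']))}: {e['msg']}"
                + (f" (allowed scenarios: {allowed})" if e["loc"][:1] == ("scenario",) else "")
                for e in exc.errors()
            ]
        return None, [
            f"{'.'.join(map(str, e['loc']))}: {e['msg']}" for e in exc.errors()
        ]


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_vtesi(block: VtesiBlock, seed: int, out: Path) -> dict:
    thermo = synthetic.TwoRegimeThermo(
        breakpoint_temperature=block.breakpoint_temperature,
        dH_low=block.dH_low,
        dH_high=block.dH_high,
        mTdS_ref_high=block.mTdS_ref_high,
        reference_temperature_high=block.reference_temperature,
        reference_temperature_low=block.reference_temperature,
    )
    temperatures = np.arange(
        block.temperature_start,
        block.temperature_stop + block.temperature_step / 2,
        block.temperature_step,
    )
    table = synthetic.generate_vant_hoff_intensities(
        thermo,
        temperatures,
        monomer_intensity=block.monomer_intensity,
        tmao_concentration=block.tmao_concentration,
        noise=synthetic.NoiseSpec(replicates=block.replicates, cv=block.cv, seed=seed),
    )
    table.to_csv(out / "intensity_table.csv", index=False)
    series = msthermo.build_vant_hoff_series(
        table, block.reaction, block.tmao_concentration
    )
    if block.breakpoint_mode == "fixed":
        fit = msthermo.fit_two_regime(series, [block.fixed_breakpoint])
    else:
        fit = msthermo.fit_two_regime(series)
    report = msthermo.thermo_report(fit, block.reference_temperature, block.reaction)
    report.to_csv(out / "thermo_report.csv", index=False)
    low = msthermo.thermo_from_fit(fit.low_regime, block.reference_temperature)
    high = msthermo.thermo_from_fit(fit.high_regime, block.reference_temperature)
    return {
        "breakpoint_K": fit.breakpoint,
        "degenerate": fit.degenerate_flag,
        "low_regime": {"dH_kJmol": low.dH, "mTdS_kJmol": low.mTdS_at_ref, "dG_kJmol": low.dG_at_ref},
        "high_regime": {"dH_kJmol": high.dH, "mTdS_kJmol": high.mTdS_at_ref, "dG_kJmol": high.dG_at_ref},
    }


def _run_trajectory(block: TrajectoryBlock, seed: int, out: Path) -> dict:
    if block.input_csv:
        traj = trajectory.ComTrajectory.from_csv(
            block.input_csv, temperature=block.temperature
        )
    else:
        potential = synthetic.PotentialSpec(
            form=block.potential.form,
            params=block.potential.params,
            bounds=tuple(block.potential.bounds),
        )
        traj = synthetic.generate_langevin_com_trajectory(
            potential,
            temperature=block.temperature,
            dt=block.dt,
            n_steps=block.n_steps,
            diffusion_coefficient=block.diffusion_coefficient,
            seed=seed,
        )
        traj.to_csv(out / "com_trajectory.csv")
    labels = trajectory.classify_states(
        traj, block.dimer_threshold, block.monomer_threshold
    )
    occupancy = trajectory.state_occupancy(labels)
    with (out / "state_occupancy.csv").open("w") as fh:
        fh.write("state,probability\n")
        for state, p in occupancy.items():
            fh.write(f"{state},{p:.6f}\n")
    normalized = trajectory.normalize_coordinate(traj)
    fep = trajectory.bootstrap_fep(
        normalized,
        traj.temperature,
        n_bins=block.n_bins,
        min_count=block.min_count,
        n_boot=block.n_boot,
        block_length=block.block_length,
        seed=seed,
    )
    fep.to_frame().to_csv(out / "fep.csv", index=False)
    finite = np.nan_to_num(fep.free_energy, nan=-np.inf)
    return {
        "occupancy": occupancy,
        "fep_barrier_kJmol": float(np.max(finite)),
        "n_frames": len(traj),
    }


def _run_census(block: CensusBlock, seed: int, out: Path) -> dict:
    pairs = [
        (
            census_mod.PeptideSpecies(
                e.sequence, e.order, e.charge, e.amide, e.adduct_mass
            ),
            e.abundance,
        )
        for e in block.species
    ]
    peaks = synthetic.generate_peak_list(
        pairs,
        peak_fwhm=block.peak_fwhm,
        mz_range=(block.mz_low, block.mz_high),
        noise_floor=block.noise_floor,
        seed=seed,
    )
    peaks.to_csv(out / "peak_list.csv", index=False)
    assignments = census_mod.assign_peaks(
        peaks, [sp for sp, _ in pairs], block.tolerance
    )
    abundances = census_mod.oligomer_abundances(
        assignments, block.max_order, block.degree_definition
    )
    with (out / "oligomer_abundances.csv").open("w") as fh:
        fh.write("order,intensity\n")
        for order, intensity in abundances.per_order.items():
            fh.write(f"{order},{intensity:.6g}\n")
    return {
        "degree_of_oligomerization": abundances.degree_of_oligomerization,
        "unassigned_fraction": abundances.unassigned_fraction,
        "per_order": {str(k): v for k, v in abundances.per_order.items()},
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the configured scenario; return (and write) the summary."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.model_dump()
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    summary: dict = {
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": _config_hash(config),
    }
    stages = {
        "vtesi_thermo": [("vtesi_thermo", _run_vtesi, config.vtesi)],
        "trajectory": [("trajectory", _run_trajectory, config.trajectory)],
        "census": [("census", _run_census, config.census)],
        "full": [
            ("vtesi_thermo", _run_vtesi, config.vtesi),
            ("trajectory", _run_trajectory, config.trajectory),
            ("census", _run_census, config.census),
        ],
    }[config.scenario]
    for name, runner, block in stages:
        logger.info("running stage %s", name)
        try:
            summary[name] = runner(block, config.seed, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
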