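"""Synthetic-data generators for every pipeline input.

All generators are pure functions of their parameters and a seed:
temperature-resolved intensity tables following a continuous two-regime
van't Hoff law, overdamped Langevin trajectories on known 1-D potentials,
exact hydrogen-bond micro-geometries, ideal-gas coordinate sets, and
Gaussian-peak spectra at theoretical oligomer m/z positions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .census import PeptideSpecies
from .constants import R_KJ
from .frames import CoordinateFrame, CoordinateFrameSet
from .msthermo import INTENSITY_COLUMNS
from .trajectory import ComTrajectory

TEMPERATURE_RANGE = (270.0, 370.0)


@dataclass
class TwoRegimeThermo:
    """Continuous two-regime van't Hoff model.

    Each regime obeys ln Ka = -dH/(R*T) + dS/R. The high regime is anchored
    by its enthalpy and the entropic term -T*dS evaluated at a reference
    temperature; the low regime shares the value of ln Ka at the breakpoint
    (continuity), so only its enthalpy is free — the regimes differ in slope,
    not in level. The implied low-regime -T*dS at its reference temperature
    is available as ``mTdS_ref_low``.
    """

    breakpoint_temperature: float  # K
    dH_low: float  # kJ/mol
    dH_high: float  # kJ/mol
    mTdS_ref_high: float  # kJ/mol, -T*dS at reference_temperature_high
    reference_temperature_high: float = 293.0  # K
    reference_temperature_low: float = 293.0  # K

    def __post_init__(self) -> None:
        if self.reference_temperature_high <= 0:
            raise ValueError("reference temperature must be positive")

    @property
    def dS_high(self) -> float:
        return -self.mTdS_ref_high / self.reference_temperature_high

    @property
    def dS_low(self) -> float:
        # continuity of ln Ka at the breakpoint fixes the low-regime entropy
        tb = self.breakpoint_temperature
        return self.dS_high + (self.dH_low - self.dH_high) / tb

    @property
    def mTdS_ref_low(self) -> float:
        return -self.reference_temperature_low * self.dS_low

    def ln_ka(self, temperature) -> np.ndarray:
        """ln Ka(T); low regime below the breakpoint, high at or above it."""
        t = np.asarray(temperature, float)
        low = -self.dH_low / (R_KJ * t) + self.dS_low / R_KJ
        high = -self.dH_high / (R_KJ * t) + self.dS_high / R_KJ
        return np.where(t < self.breakpoint_temperature, low, high)

    @classmethod
    def single_regime(
        cls, dH: float, mTdS_ref: float, reference_temperature: float = 293.0
    ) -> "TwoRegimeThermo":
        """A degenerate model with one slope everywhere."""
        return cls(
            breakpoint_temperature=reference_temperature,
            dH_low=dH,
            dH_high=dH,
            mTdS_ref_high=mTdS_ref,
            reference_temperature_high=reference_temperature,
            reference_temperature_low=reference_temperature,
        )


@dataclass
class NoiseSpec:
    """Replicate structure and multiplicative noise level."""

    replicates: int = 3
    cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


def generate_vant_hoff_intensities(
    thermo: TwoRegimeThermo,
    temperatures,
    monomer_intensity: float = 1000.0,
    tmao_concentration: float = 5e-4,
    noise: NoiseSpec | None = None,
) -> pd.DataFrame:
    """Intensity table whose Ka ratios follow the two-regime model exactly.

    For each temperature and replicate the monomer intensity is the supplied
    baseline, the dimer intensity is Ka(T) * I_monomer**2, and the
    SP-TMAO-complex intensity is Ka(T) * I_monomer * [TMAO], so the
    downstream ratio formulas invert to ln Ka(T) exactly at zero noise.
    Noise is multiplicative log-normal with unit mean and the requested
    linear-scale coefficient of variation, applied independently per row.
    """
    if noise is None:
        noise = NoiseSpec()
    temperatures = np.asarray(temperatures, float)
    lo, hi = TEMPERATURE_RANGE
    if np.any((temperatures < lo) | (temperatures > hi)):
        raise ValueError(f"temperatures must lie within {lo}-{hi} K")
    if monomer_intensity <= 0:
        raise ValueError("monomer_intensity must be positive")
    if tmao_concentration <= 0:
        raise ValueError("tmao_concentration must be positive")
    rng = np.random.default_rng(noise.seed)
    sigma = math.sqrt(math.log(1.0 + noise.cv**2))
    rows = []
    for temperature in temperatures:
        ka = float(np.exp(thermo.ln_ka(temperature)))
        for replicate in range(1, noise.replicates + 1):
            base = {
                "monomer": monomer_intensity,
                "dimer": ka * monomer_intensity**2,
                "sp_tmao_complex": ka * monomer_intensity * tmao_concentration,
            }
            for species, intensity in base.items():
                if noise.cv > 0:
                    factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
                else:
                    factor = 1.0
                rows.append(
                    {
                        "temperature_K": float(temperature),
                        "replicate": replicate,
                        "species": species,
                        "intensity": intensity * factor,
                    }
                )
    return pd.DataFrame(rows, columns=INTENSITY_COLUMNS)


@dataclass
class PotentialSpec:
    """1-D potential for the Langevin generator.

    Forms: ``flat``; ``harmonic`` (params: center nm, stiffness kJ/mol/nm^2);
    ``double_well`` (params: well_1, well_2 nm, barrier kJ/mol, optional
    tilt kJ/mol added linearly across the well separation); ``tabulated``
    (params: x, u arrays, linearly interpolated).
    """

    form: str
    params: dict = field(default_factory=dict)
    bounds: tuple[float, float] = (0.0, 4.0)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must be ordered")
        if self.form not in ("flat", "harmonic", "double_well", "tabulated"):
            raise ValueError(f"unknown potential form: {self.form!r}")
        probe = self.energy(np.linspace(lo, hi, 257))
        if not np.all(np.isfinite(probe)):
            raise ValueError("potential not finite on its domain")

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            c = self.params.get("center", 0.5 * sum(self.bounds))
            k = self.params["stiffness"]
            return 0.5 * k * (x - c) ** 2
        if self.form == "double_well":
            x1, x2 = self.params["well_1"], self.params["well_2"]
            h = self.params["barrier"]
            tilt = self.params.get("tilt", 0.0)
            half = 0.5 * (x2 - x1)
            u = h * ((x - x1) * (x - x2)) ** 2 / half**4
            return u + tilt * (x - x1) / (x2 - x1)
        xs = np.asarray(self.params["x"], float)
        us = np.asarray(self.params["u"], float)
        return np.interp(x, xs, us)

    def force(self, x) -> np.ndarray:
        """-dU/dx, analytic where available, central difference otherwise."""
        x = np.asarray(x, float)
        if self.form == "flat":
            return np.zeros_like(x)
        if self.form == "harmonic":
            c = self.params.get("center", 0.5 * sum(self.bounds))
            k = self.params["stiffness"]
            return -k * (x - c)
        if self.form == "double_well":
            x1, x2 = self.params["well_1"], self.params["well_2"]
            h = self.params["barrier"]
            tilt = self.params.get("tilt", 0.0)
            half = 0.5 * (x2 - x1)
            poly = (x - x1) * (x - x2)
            dpoly = 2.0 * x - x1 - x2
            return -2.0 * h * poly * dpoly / half**4 - tilt / (x2 - x1)
        eps = 1e-6 * (self.bounds[1] - self.bounds[0])
        return -(self.energy(x + eps) - self.energy(x - eps)) / (2 * eps)


def generate_langevin_com_trajectory(
    potential: PotentialSpec,
    temperature: float,
    dt: float,
    n_steps: int,
    diffusion_coefficient: float = 1.0,
    seed: int = 0,
    x0: float | None = None,
    sample_stride: int = 1,
) -> ComTrajectory:
    """Overdamped Langevin trajectory with reflecting domain boundaries.

    Update: x += D*f(x)/(R*T) * dt + sqrt(2*D*dt) * N(0,1), reflected at the
    domain bounds; the stationary law is proportional to exp(-U/(R*T)).
    A dt producing a deterministic drift above 10% of the domain anywhere
    is rejected.
    """
    if dt <= 0 or n_steps < 1 or diffusion_coefficient <= 0:
        raise ValueError("dt, n_steps, and diffusion_coefficient must be positive")
    lo, hi = potential.bounds
    beta = 1.0 / (R_KJ * temperature)
    grid = np.linspace(lo, hi, 513)
    drift = np.abs(beta * diffusion_coefficient * potential.force(grid) * dt)
    if drift.max() > 0.1 * (hi - lo):
        raise ValueError("dt too large: drift per step exceeds 10% of the domain")
    rng = np.random.default_rng(seed)
    noise_scale = math.sqrt(2.0 * diffusion_coefficient * dt)
    kicks = rng.normal(0.0, noise_scale, size=n_steps)
    mobility = beta * diffusion_coefficient * dt
    x = 0.5 * (lo + hi) if x0 is None else float(x0)
    force = potential.force
    out = np.empty(n_steps // sample_stride + 1)
    out[0] = x
    j = 1
    width = hi - lo
    for i in range(n_steps):
        x = x + mobility * float(force(x)) + kicks[i]
        # reflect into [lo, hi]
        if x < lo or x > hi:
            x = (x - lo) % (2.0 * width)
            x = lo + (x if x <= width else 2.0 * width - x)
        if (i + 1) % sample_stride == 0:
            out[j] = x
            j += 1
    out = out[:j]
    interval = dt * sample_stride
    times = np.arange(len(out)) * interval
    return ComTrajectory(
        times=times,
        distances=out,
        temperature=temperature,
        frame_interval=interval,
    )


D_H_BOND_LENGTH = 0.1  # nm, covalent donor-hydrogen distance used in fixtures


def generate_hbond_geometry(
    donor_acceptor_distance: float, deviation_angle: float
) -> CoordinateFrame:
    """Donor, hydrogen, acceptor realizing an exact distance and deviation.

    The donor sits at the origin with the hydrogen 0.1 nm along +x; the
    acceptor is placed in the xy-plane so the donor-acceptor distance and
    the deviation of the D-H-A angle from linearity match the request
    exactly. Raises when no such placement exists.
    """
    if donor_acceptor_distance <= 0:
        raise ValueError("distance must be positive")
    if not (0 <= deviation_angle <= 180):
        raise ValueError("deviation angle must be in [0, 180] degrees")
    r = donor_acceptor_distance
    d = D_H_BOND_LENGTH
    theta = math.radians(deviation_angle)
    disc = r**2 - d**2 * math.sin(theta) ** 2
    if disc < 0:
        raise ValueError("geometrically impossible distance/angle combination")
    length = -d * math.cos(theta) + math.sqrt(disc)
    if length <= 0:
        raise ValueError("geometrically impossible: acceptor collapses onto hydrogen")
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([d, 0.0, 0.0])
    acceptor = hydrogen + length * np.array([math.cos(theta), math.sin(theta), 0.0])
    return CoordinateFrame(["D", "H", "A"], np.vstack([donor, hydrogen, acceptor]))


def generate_ideal_gas_coordinates(
    n_particles: int, box_edge: float, seed: int = 0, n_frames: int = 1
) -> CoordinateFrameSet:
    """Uniform uncorrelated positions in a periodic cube (RDF null model)."""
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    rng = np.random.default_rng(seed)
    names = [f"P{i}" for i in range(n_particles)]
    frames = [
        CoordinateFrame(names, rng.uniform(0.0, box_edge, size=(n_particles, 3)))
        for _ in range(n_frames)
    ]
    return CoordinateFrameSet(frames, box_edge=box_edge)


def generate_peak_list(
    species,
    peak_fwhm: float,
    mz_range: tuple[float, float],
    noise_floor: float = 0.0,
    seed: int = 0,
    grid_step: float | None = None,
) -> pd.DataFrame:
    """Profile spectrum of Gaussian peaks at theoretical species m/z.

    ``species`` entries are PeptideSpecies or (sequence, order, charge,
    abundance) tuples (amidated C-terminus assumed for tuples). Each peak
    integrates to its abundance; an additive uniform noise floor in
    [0, noise_floor] is applied pointwise. Species closer than fwhm/2 are
    flagged with a warning.
    """
    if peak_fwhm <= 0:
        raise ValueError("peak_fwhm must be positive")
    entries: list[tuple[PeptideSpecies, float]] = []
    for item in species:
        if len(item) == 4 and isinstance(item[0], str):
            seq, order, charge, abundance = item
            entries.append((PeptideSpecies(seq, order, charge), float(abundance)))
        else:
            sp, abundance = item
            entries.append((sp, float(abundance)))
    if any(a < 0 for _, a in entries):
        raise ValueError("abundances must be non-negative")
    centers = np.array([sp.mz for sp, _ in entries])
    order = np.argsort(centers)
    sorted_centers = centers[order]
    gaps = np.diff(sorted_centers)
    if np.any(gaps < peak_fwhm / 2):
        close = sorted_centers[:-1][gaps < peak_fwhm / 2]
        warnings.warn(
            f"species closer than fwhm/2 near m/z {np.round(close, 3).tolist()}; "
            "assignments may be ambiguous",
            stacklevel=2,
        )
    step = grid_step if grid_step is not None else peak_fwhm / 10.0
    lo, hi = mz_range
    grid = np.arange(lo, hi + step / 2, step)
    sigma = peak_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    intensity = np.zeros_like(grid)
    for (sp, abundance), center in zip(entries, centers):
        if abundance == 0:
            continue
        intensity += (
            abundance
            / (sigma * math.sqrt(2.0 * math.pi))
            * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        )
    if noise_floor > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.uniform(0.0, noise_floor, size=len(grid))
    return pd.DataFrame({"mz": grid, "intensity": intensity})
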