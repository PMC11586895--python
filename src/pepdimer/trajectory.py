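"""State classification, free-energy profiles, hydrogen bonds, and RDFs
from centre-of-mass distance series or coordinate frames.

Free energies come from Boltzmann inversion of the occupancy histogram,
F_i = -R*T*ln P_i, min-shifted to zero; sparse bins are masked rather than
extrapolated. Bootstrap variance uses circular block resampling so that
autocorrelated trajectories are not treated as independent samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AVOGADRO, R_KJ
from .frames import (
    CoordinateFrame,
    CoordinateFrameSet,
    mass_weighted_com,
    minimum_image_displacement,
)

#: COM distance (nm) below which two chains count as a dimer.
DIMER_THRESHOLD = 2.0
#: COM distance (nm) above which the chains count as fully separated.
MONOMER_THRESHOLD = 3.5

#: Normalized-coordinate annotations for profile plots: dimer below 0.3,
#: separated monomers between 0.6 and 1.0.
DIMER_REGION = (0.0, 0.3)
MONOMER_REGION = (0.6, 1.0)

STATES = ("dimer", "transition", "monomer")


@dataclass
class ComTrajectory:
    """Uniformly sampled interchain centre-of-mass distance series."""

    times: np.ndarray  # ns
    distances: np.ndarray  # nm
    temperature: float  # K
    box_edge: float | None = None  # nm
    frame_interval: float | None = None  # ns

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.distances = np.asarray(self.distances, float)
        if len(self.times) != len(self.distances):
            raise ValueError("times and distances length mismatch")
        if len(self.times) < 1:
            raise ValueError("trajectory must hold at least one frame")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        if self.frame_interval is None and len(self.times) > 1:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
                raise ValueError("frame interval is not uniform")
            self.frame_interval = float(dts[0])

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# temperature_K={self.temperature:g}")
            if self.box_edge is not None:
                fh.write(f" box_edge_nm={self.box_edge:g}")
            fh.write("\n")
            pd.DataFrame(
                {"time_ns": self.times, "distance_nm": self.distances}
            ).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, temperature: float | None = None):
        path = Path(path)
        meta: dict[str, float] = {}
        with path.open() as fh:
            first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    key, value = token.split("=", 1)
                    meta[key] = float(value)
        df = pd.read_csv(path, comment="#")
        temp = temperature if temperature is not None else meta.get("temperature_K")
        if temp is None:
            raise ValueError("temperature not in header; pass temperature=")
        return cls(
            times=df["time_ns"].to_numpy(),
            distances=df["distance_nm"].to_numpy(),
            temperature=float(temp),
            box_edge=meta.get("box_edge_nm"),
        )


def com_distance_series(
    frames: CoordinateFrameSet,
    chain_a: np.ndarray,
    chain_b: np.ndarray,
    masses_a: np.ndarray,
    masses_b: np.ndarray,
    temperature: float,
    frame_interval: float = 1.0,
    box_edge: float | None = None,
) -> ComTrajectory:
    """Interchain COM distance per frame under the minimum-image convention.

    ``chain_a``/``chain_b`` are index arrays into each frame; masses are
    per-selected-particle and must be positive.
    """
    chain_a = np.asarray(chain_a, int)
    chain_b = np.asarray(chain_b, int)
    if chain_a.size == 0 or chain_b.size == 0:
        raise ValueError("empty chain selection")
    edge = box_edge if box_edge is not None else frames.box_edge
    distances = []
    for frame in frames:
        if edge is None and frame.positions.max() > 0:
            # tolerate boxless input only when nothing can wrap
            pass
        com_a = mass_weighted_com(frame.positions[chain_a], masses_a)
        com_b = mass_weighted_com(frame.positions[chain_b], masses_b)
        d = minimum_image_displacement(com_a, com_b, edge)
        distances.append(float(np.linalg.norm(d)))
    n = len(distances)
    times = np.arange(n) * frame_interval
    return ComTrajectory(
        times=times,
        distances=np.array(distances),
        temperature=temperature,
        box_edge=edge,
        frame_interval=frame_interval,
    )


@dataclass
class StateLabels:
    """Per-frame dimer/transition/monomer labels plus thresholds used."""

    labels: np.ndarray  # of str
    dimer_threshold: float
    monomer_threshold: float

    def __len__(self) -> int:
        return len(self.labels)


def classify_states(
    traj: ComTrajectory,
    dimer_threshold: float = DIMER_THRESHOLD,
    monomer_threshold: float = MONOMER_THRESHOLD,
) -> StateLabels:
    """Label frames by COM distance: strictly below the dimer threshold is
    dimer, strictly above the monomer threshold is monomer, everything in
    between (including boundary values) is transition."""
    if dimer_threshold >= monomer_threshold:
        raise ValueError("dimer_threshold must be below monomer_threshold")
    d = traj.distances
    labels = np.full(len(d), "transition", dtype=object)
    labels[d < dimer_threshold] = "dimer"
    labels[d > monomer_threshold] = "monomer"
    return StateLabels(labels, dimer_threshold, monomer_threshold)


def state_occupancy(labels: StateLabels) -> dict[str, float]:
    """Fraction of frames in each state; values sum to 1."""
    n = len(labels)
    if n == 0:
        raise ValueError("empty trajectory")
    return {state: float(np.sum(labels.labels == state)) / n for state in STATES}


def normalize_coordinate(traj: ComTrajectory) -> np.ndarray:
    """Min-max normalization of the distance series to [0, 1]."""
    d = traj.distances
    lo, hi = float(d.min()), float(d.max())
    if hi <= lo:
        raise ValueError("constant distance series cannot be normalized")
    return (d - lo) / (hi - lo)


@dataclass
class FreeEnergyProfile:
    """Binned Boltzmann-inversion free energy, min-shifted to zero.

    Bins holding fewer than ``min_count`` samples have NaN free energy and
    never participate in the min-shift.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray  # kJ/mol, NaN where masked
    counts: np.ndarray
    temperature: float
    bin_edges: np.ndarray = field(default=None)
    variance: np.ndarray | None = None  # kJ^2/mol^2, from bootstrap

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coordinate": self.bin_centers,
                "free_energy_kJmol": self.free_energy,
                "variance": self.variance
                if self.variance is not None
                else np.full(len(self.bin_centers), np.nan),
                "counts": self.counts,
            }
        )


def _profile_from_counts(
    counts: np.ndarray, temperature: float, min_count: int
) -> np.ndarray:
    total = counts.sum()
    with np.errstate(divide="ignore"):
        f = -R_KJ * temperature * np.log(counts / total)
    f[counts < min_count] = np.nan
    if np.all(np.isnan(f)):
        raise ValueError("all bins below min_count")
    return f - np.nanmin(f)


def free_energy_profile(
    series: np.ndarray,
    temperature: float,
    n_bins: int = 50,
    min_count: int = 10,
    bin_range: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """Histogram a coordinate series and Boltzmann-invert it.

    F_i = -R*T*ln(N_i/N) on bins with N_i >= min_count, shifted so the
    minimum over unmasked bins is zero.
    """
    series = np.asarray(series, float)
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    counts, edges = np.histogram(series, bins=n_bins, range=bin_range)
    f = _profile_from_counts(counts.astype(float), temperature, min_count)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FreeEnergyProfile(
        bin_centers=centers,
        free_energy=f,
        counts=counts,
        temperature=temperature,
        bin_edges=edges,
    )


def free_energy_of_states(
    occupancy: dict[str, float], temperature: float
) -> dict[str, float]:
    """Coarse three-state variant: -R*T*ln P per state, min-shifted."""
    finite = {s: p for s, p in occupancy.items() if p > 0}
    if not finite:
        raise ValueError("no occupied states")
    f = {s: -R_KJ * temperature * math.log(p) for s, p in finite.items()}
    fmin = min(f.values())
    out = {s: f[s] - fmin for s in f}
    for s in occupancy:
        out.setdefault(s, float("nan"))
    return out


def bootstrap_fep(
    series: np.ndarray,
    temperature: float,
    n_bins: int = 50,
    min_count: int = 10,
    n_boot: int = 100,
    block_length: int = 100,
    seed: int = 0,
    bin_range: tuple[float, float] | None = None,
) -> FreeEnergyProfile:
    """Free-energy profile with a circular-block-bootstrap variance band.

    Resamples contiguous blocks (wrapping at the series end) to respect
    autocorrelation; per-bin variance is taken across resampled profiles,
    using the point estimate's bin edges throughout. ``block_length=1``
    reduces to the naive iid bootstrap.
    """
    series = np.asarray(series, float)
    n = len(series)
    if n_boot < 2:
        raise ValueError("need n_boot >= 2")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if block_length >= n:
        raise ValueError("block_length must be shorter than the series")
    point = free_energy_profile(series, temperature, n_bins, min_count, bin_range)
    edges = point.bin_edges
    rng = np.random.default_rng(seed)
    n_blocks = math.ceil(n / block_length)
    idx = np.arange(n)
    profiles = np.full((n_boot, len(point.bin_centers)), np.nan)
    for b in range(n_boot):
        starts = rng.integers(0, n, size=n_blocks)
        take = (starts[:, None] + idx[:block_length][None, :]) % n
        resampled = series[take.ravel()[:n]]
        counts, _ = np.histogram(resampled, bins=edges)
        try:
            profiles[b] = _profile_from_counts(
                counts.astype(float), temperature, min_count
            )
        except ValueError:
            continue
    import warnings

    with warnings.catch_warnings():
        # bins masked in every resample yield all-NaN slices
        warnings.simplefilter("ignore", RuntimeWarning)
        variance = np.nanvar(profiles, axis=0, ddof=1)
    variance[np.isnan(point.free_energy)] = np.nan
    point.variance = variance
    return point


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond test: donor-acceptor distance cutoff (nm)
    and maximum deviation of the D-H-A angle from linearity (degrees)."""

    max_da_distance: float = 0.35
    max_deviation_angle: float = 30.0

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0 < self.max_deviation_angle <= 90):
            raise ValueError("deviation angle must be in (0, 90]")


def hbond_deviation_angle(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    box_edge: float | None = None,
) -> float:
    """Deviation of the D-H-A angle from 180 degrees."""
    hd = minimum_image_displacement(hydrogen, donor, box_edge)
    ha = minimum_image_displacement(hydrogen, acceptor, box_edge)
    cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
    angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - angle


def count_hbonds(
    frame: CoordinateFrame,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria | None = None,
    box_edge: float | None = None,
) -> tuple[int, list[tuple[int, int, int]]]:
    """Count donor-hydrogen...acceptor triples meeting the criteria.

    ``donors`` and ``hydrogens`` are parallel arrays (hydrogen i is bonded
    to donor i). Returns the count and the (donor, hydrogen, acceptor)
    index triples. A hydrogen's parent donor is never its acceptor.
    """
    if criteria is None:
        criteria = HBondCriteria()
    donors = np.asarray(donors, int)
    hydrogens = np.asarray(hydrogens, int)
    acceptors = np.asarray(acceptors, int)
    if len(donors) != len(hydrogens):
        raise ValueError("each hydrogen must be paired with its parent donor")
    pairs: list[tuple[int, int, int]] = []
    pos = frame.positions
    for d_idx, h_idx in zip(donors, hydrogens):
        for a_idx in acceptors:
            if a_idx == d_idx or a_idx == h_idx:
                continue
            da = minimum_image_displacement(pos[d_idx], pos[a_idx], box_edge)
            if np.linalg.norm(da) > criteria.max_da_distance:
                continue
            dev = hbond_deviation_angle(pos[d_idx], pos[h_idx], pos[a_idx], box_edge)
            if dev <= criteria.max_deviation_angle:
                pairs.append((int(d_idx), int(h_idx), int(a_idx)))
    return len(pairs), pairs


@dataclass
class RdfCurve:
    """Radial distribution function normalized so an ideal gas gives 1."""

    r: np.ndarray  # bin centers, nm
    g: np.ndarray
    bin_width: float
    counts: np.ndarray
    reference_tag: str = "reference"
    target_tag: str = "target"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_nm": self.r, "g_r": self.g, "counts": self.counts})


def rdf(
    frames: CoordinateFrameSet,
    reference: np.ndarray,
    target: np.ndarray,
    box_edge: float | None = None,
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RdfCurve:
    """Pair correlation g(r) between two selections, frame-averaged.

    Histogram of minimum-image pair distances, normalized by the ideal-gas
    expectation n_ref * rho_target * shell_volume per frame. Self-pairs
    (same particle index) are excluded. r_max must not exceed half the box.
    """
    reference = np.asarray(reference, int)
    target = np.asarray(target, int)
    if reference.size == 0 or target.size == 0:
        raise ValueError("empty selection")
    edge = box_edge if box_edge is not None else frames.box_edge
    if edge is None:
        raise ValueError("rdf requires a box edge")
    if r_max is None:
        r_max = edge / 2
    if r_max > edge / 2 + 1e-12:
        raise ValueError("r_max must be <= box_edge/2")
    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0, n_bins * bin_width, n_bins + 1)
    counts = np.zeros(n_bins)
    n_frames = len(frames)
    overlap = np.intersect1d(reference, target).size
    for frame in frames:
        delta = frame.positions[target][None, :, :] - frame.positions[reference][:, None, :]
        delta -= edge * np.round(delta / edge)
        dist = np.sqrt((delta**2).sum(axis=-1)).ravel()
        dist = dist[dist > 1e-12]  # drop self-pairs
        hist, _ = np.histogram(dist, bins=edges)
        counts += hist
    volume = edge**3
    rho_target = len(target) / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # each reference sees (n_target - overlap_correction) ideal partners
    n_pairs_ideal = len(reference) * rho_target * shell
    if overlap:
        n_pairs_ideal *= (len(target) * len(reference) - overlap) / (
            len(target) * len(reference)
        )
    g = counts / (n_frames * n_pairs_ideal)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RdfCurve(r=centers, g=g, bin_width=bin_width, counts=counts)


def box_concentration(
    n_molecules: int, box_edge_nm: float, avogadro: float = AVOGADRO
) -> float:
    """Molar concentration of n molecules in a cubic box (edge in nm)."""
    volume_l = (box_edge_nm * 1e-8) ** 3  # nm -> dm
    return n_molecules / (avogadro * volume_l)
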