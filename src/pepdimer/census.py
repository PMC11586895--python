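"""Theoretical oligomer m/z, peak assignment, and oligomerization degree.

Masses are monoisotopic by default (an average-mass mode covers
low-resolution labels). The degree of oligomerization is the
monomer-equivalent mass fraction of signal residing in oligomers,

    degree = sum_{n>=2} n*I_n / sum_{n>=1} n*I_n,

with a simple signal-fraction alternative selectable by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AMIDE_CORRECTION, PROTON_MASS, WATER_MONO

# Monoisotopic residue masses (peptide-bond residues), Da.
MONO_RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

# Average residue masses, Da.
AVG_RESIDUE_MASS = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

WATER_AVG = 18.01528

#: Substance P sequence (amidated C-terminus in the native peptide).
SP_SEQUENCE = "RPKPQQFFGLM"


def peptide_mass(
    sequence: str, c_terminal_amide: bool = False, monoisotopic: bool = True
) -> float:
    """Neutral peptide mass: residue sum + water, minus 0.98402 Da if amidated."""
    table = MONO_RESIDUE_MASS if monoisotopic else AVG_RESIDUE_MASS
    water = WATER_MONO if monoisotopic else WATER_AVG
    mass = water
    for letter in sequence:
        try:
            mass += table[letter]
        except KeyError:
            raise ValueError(f"unknown residue letter: {letter!r}") from None
    if c_terminal_amide:
        mass += AMIDE_CORRECTION
    return mass


def theoretical_mz(
    sequence: str,
    oligomer_order: int = 1,
    charge: int = 1,
    c_terminal_amide: bool = False,
    adduct_mass: float = 0.0,
    monoisotopic: bool = True,
) -> float:
    """m/z of an n-mer: (n*M + adduct + z*m_proton) / z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    if oligomer_order < 1:
        raise ValueError("oligomer_order must be >= 1")
    neutral = peptide_mass(sequence, c_terminal_amide, monoisotopic)
    return (oligomer_order * neutral + adduct_mass + charge * PROTON_MASS) / charge


@dataclass
class PeptideSpecies:
    """One charge state of one oligomer order of one sequence."""

    sequence: str
    oligomer_order: int = 1
    charge: int = 1
    c_terminal_amide: bool = True
    adduct_mass: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            adduct = "+adduct" if self.adduct_mass else ""
            self.label = (
                f"{self.sequence}_n{self.oligomer_order}_z{self.charge}{adduct}"
            )

    @property
    def mz(self) -> float:
        return theoretical_mz(
            self.sequence,
            self.oligomer_order,
            self.charge,
            self.c_terminal_amide,
            self.adduct_mass,
        )


def read_species_table(path: str | Path) -> list[PeptideSpecies]:
    """Species CSV: sequence, order, charge, amide flag, adduct_mass."""
    df = pd.read_csv(path)
    species = []
    for _, row in df.iterrows():
        species.append(
            PeptideSpecies(
                sequence=str(row["sequence"]),
                oligomer_order=int(row["order"]),
                charge=int(row["charge"]),
                c_terminal_amide=bool(row.get("amide", True)),
                adduct_mass=float(row.get("adduct_mass", 0.0) or 0.0),
            )
        )
    return species


def validate_peak_list(peaks: pd.DataFrame) -> pd.DataFrame:
    if not {"mz", "intensity"} <= set(peaks.columns):
        raise ValueError("peak list needs 'mz' and 'intensity' columns")
    if (peaks["intensity"] < 0).any():
        raise ValueError("negative peak intensities")
    if not peaks["mz"].is_monotonic_increasing:
        peaks = peaks.sort_values("mz").reset_index(drop=True)
    return peaks


def read_peak_list(path: str | Path) -> pd.DataFrame:
    return validate_peak_list(pd.read_csv(path, comment="#"))


@dataclass
class PeakAssignments:
    """Result of nearest-species peak assignment.

    ``per_species`` maps species label -> aggregated intensity;
    ``unassigned`` is the total intensity not claimed by any species;
    ``ambiguous_peaks`` holds the indices of peaks split between species.
    """

    per_species: dict[str, float]
    species: list[PeptideSpecies]
    unassigned: float
    total: float
    ambiguous_peaks: list[int] = field(default_factory=list)


def assign_peaks(
    peaks: pd.DataFrame, species: list[PeptideSpecies], tolerance: float
) -> PeakAssignments:
    """Assign each peak to species within an m/z tolerance.

    A peak within tolerance of one species goes to it entirely; within
    tolerance of several, its intensity is split by inverse-distance
    weights (exact hits take everything) and the peak is flagged as
    ambiguous. Intensity is conserved: assigned + unassigned = total.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    peaks = validate_peak_list(peaks)
    mz_targets = np.array([s.mz for s in species])
    labels = [s.label for s in species]
    per_species = {label: 0.0 for label in labels}
    unassigned = 0.0
    ambiguous: list[int] = []
    for idx, (mz, intensity) in enumerate(
        zip(peaks["mz"].to_numpy(), peaks["intensity"].to_numpy())
    ):
        dist = np.abs(mz_targets - mz)
        within = np.flatnonzero(dist <= tolerance)
        if within.size == 0:
            unassigned += intensity
            continue
        if within.size > 1:
            ambiguous.append(idx)
        exact = within[dist[within] < 1e-12]
        if exact.size:
            share = intensity / exact.size
            for j in exact:
                per_species[labels[j]] += share
        else:
            weights = 1.0 / dist[within]
            weights /= weights.sum()
            for j, w in zip(within, weights):
                per_species[labels[j]] += intensity * w
    total = float(peaks["intensity"].sum())
    return PeakAssignments(
        per_species=per_species,
        species=list(species),
        unassigned=float(unassigned),
        total=total,
        ambiguous_peaks=ambiguous,
    )


@dataclass
class OligomerAbundances:
    """Summed assigned intensity per oligomer order plus the degree statistic."""

    per_order: dict[int, float]
    degree_of_oligomerization: float
    unassigned_fraction: float


def oligomer_abundances(
    assignments: PeakAssignments,
    max_order: int = 3,
    definition: str = "mass_fraction",
) -> OligomerAbundances:
    """Aggregate assigned intensity per oligomer order and score oligomerization.

    ``definition='mass_fraction'`` weights order-n intensity by n (monomer
    equivalents); ``'signal_fraction'`` is the unweighted oligomer share.
    Orders above ``max_order`` are ignored (mirrors the order-3 software cap).
    """
    if definition not in ("mass_fraction", "signal_fraction"):
        raise ValueError("definition must be 'mass_fraction' or 'signal_fraction'")
    per_order = {n: 0.0 for n in range(1, max_order + 1)}
    for sp in assignments.species:
        if sp.oligomer_order > max_order:
            continue
        per_order[sp.oligomer_order] += assignments.per_species[sp.label]
    total_signal = sum(per_order.values())
    if total_signal <= 0:
        raise ValueError("nothing assigned within the order cap")
    if definition == "mass_fraction":
        weighted = {n: n * i for n, i in per_order.items()}
        degree = sum(v for n, v in weighted.items() if n >= 2) / sum(weighted.values())
    else:
        degree = sum(i for n, i in per_order.items() if n >= 2) / total_signal
    unassigned_fraction = (
        assignments.unassigned / assignments.total if assignments.total > 0 else 0.0
    )
    return OligomerAbundances(
        per_order=per_order,
        degree_of_oligomerization=float(degree),
        unassigned_fraction=float(unassigned_fraction),
    )


def compare_conditions(
    replicate_degrees: dict[str, list[float]],
    condition_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Mean and sd of the oligomerization degree per condition.

    Each condition needs >= 2 replicates. When ``condition_pair=(a, b)`` is
    given, a ``difference_of_means`` column (mean_a - mean_b) is attached.
    """
    rows = []
    for condition, degrees in replicate_degrees.items():
        if len(degrees) < 2:
            raise ValueError(f"condition {condition!r} has <2 replicates")
        arr = np.asarray(degrees, float)
        rows.append(
            {
                "condition": condition,
                "n": len(arr),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
            }
        )
    table = pd.DataFrame(rows)
    if condition_pair is not None:
        a, b = condition_pair
        means = table.set_index("condition")["mean"]
        table["difference_of_means"] = float(means[a] - means[b])
    return table
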