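"""Equilibrium constants and van't Hoff thermodynamics from ion intensities.

The apparent association constant for dimerization is the dimer intensity
over the squared monomer intensity (the free "ligand" is the monomer
itself); for osmolyte binding it is the complex intensity over the monomer
intensity times the osmolyte molarity. Constants carry arbitrary
inverse-intensity units; van't Hoff slopes are unaffected by the constant
unit factor, so enthalpies and entropy differences are meaningful even
though absolute molar constants are not.

The linear model fitted throughout is

    ln Ka = -dH / (R * T) + dS / R

so a regression of ln Ka on 1/T has slope -dH/R (in K) and intercept dS/R.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import R_KJ

logger = logging.getLogger(__name__)

SPECIES = ("monomer", "dimer", "sp_tmao_complex")
INTENSITY_COLUMNS = ["temperature_K", "replicate", "species", "intensity"]

REACTION_PRODUCT = {"dimerization": "dimer", "tmao_binding": "sp_tmao_complex"}


def validate_intensity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the intensity-table schema and invariants; return the table.

    Temperatures must be Kelvin; values below 150 are rejected as almost
    certainly Celsius given the instrument's 278-358 K range.
    """
    missing = [c for c in INTENSITY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"intensity table missing columns: {missing}")
    if (table["intensity"] < 0).any():
        raise ValueError("negative intensities present")
    unknown = set(table["species"]) - set(SPECIES)
    if unknown:
        raise ValueError(f"unknown species: {sorted(unknown)}")
    if (table["temperature_K"] < 150).any():
        raise ValueError("temperatures below 150 K: suspected Celsius input")
    mono = table[table["species"] == "monomer"]
    have = set(zip(mono["temperature_K"], mono["replicate"]))
    need = set(zip(table["temperature_K"], table["replicate"]))
    if need - have:
        raise ValueError("every (temperature, replicate) needs a monomer row")
    return table


def read_intensity_table(path) -> pd.DataFrame:
    return validate_intensity_table(pd.read_csv(path, comment="#"))


def compute_ka_dimer(i_dimer: float, i_monomer: float) -> float:
    """Apparent dimerization constant: I_dimer / I_monomer**2."""
    if i_monomer <= 0:
        raise ValueError("monomer intensity must be positive")
    if i_dimer < 0:
        raise ValueError("dimer intensity must be non-negative")
    return i_dimer / i_monomer**2


def compute_ka_complex(
    i_complex: float, i_monomer: float, tmao_concentration: float
) -> float:
    """Apparent osmolyte-binding constant: I_complex / (I_monomer * [TMAO])."""
    if i_monomer <= 0:
        raise ValueError("monomer intensity must be positive")
    if tmao_concentration <= 0:
        raise ValueError("tmao_concentration must be positive")
    if i_complex < 0:
        raise ValueError("complex intensity must be non-negative")
    return i_complex / (i_monomer * tmao_concentration)


@dataclass
class VantHoffSeries:
    """Per-temperature ln Ka points, sorted by inverse temperature.

    ``ln_ka_sd`` entries are NaN when fewer than two replicates survive.
    """

    inverse_temperature: np.ndarray
    ln_ka: np.ndarray
    ln_ka_sd: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.inverse_temperature)
        self.inverse_temperature = np.asarray(self.inverse_temperature, float)[order]
        self.ln_ka = np.asarray(self.ln_ka, float)[order]
        self.ln_ka_sd = np.asarray(self.ln_ka_sd, float)[order]
        self.n_replicates = np.asarray(self.n_replicates, int)[order]

    @property
    def temperatures(self) -> np.ndarray:
        return 1.0 / self.inverse_temperature

    def __len__(self) -> int:
        return len(self.ln_ka)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inverse_temperature_perK": self.inverse_temperature,
                "ln_ka": self.ln_ka,
                "ln_ka_sd": self.ln_ka_sd,
                "n_replicates": self.n_replicates,
            }
        )


def build_vant_hoff_series(
    table: pd.DataFrame,
    reaction: str = "dimerization",
    tmao_concentration: float | None = None,
    average: str = "log",
) -> VantHoffSeries:
    """Collapse an intensity table into ln Ka versus 1/T.

    Ka is computed per replicate; by default ln Ka is averaged across
    replicates (matching a multiplicative noise model). ``average='linear'``
    averages Ka before taking the log instead. Replicates whose product
    intensity is zero are dropped; temperatures losing all replicates are
    excluded, with counts logged.
    """
    if reaction not in REACTION_PRODUCT:
        raise ValueError(f"reaction must be one of {sorted(REACTION_PRODUCT)}")
    if reaction == "tmao_binding" and tmao_concentration is None:
        raise ValueError("tmao_concentration required for tmao_binding")
    if average not in ("log", "linear"):
        raise ValueError("average must be 'log' or 'linear'")
    validate_intensity_table(table)
    product = REACTION_PRODUCT[reaction]

    wide = table.pivot_table(
        index=["temperature_K", "replicate"],
        columns="species",
        values="intensity",
        aggfunc="sum",
    )
    if product not in wide.columns:
        raise ValueError(f"no '{product}' rows in table")

    inv_t, ln_mean, ln_sd, n_rep = [], [], [], []
    n_dropped = 0
    for temperature, group in wide.groupby(level="temperature_K"):
        kas = []
        for _, row in group.iterrows():
            i_product = row.get(product, np.nan)
            i_monomer = row.get("monomer", np.nan)
            if not np.isfinite(i_product) or i_product <= 0:
                n_dropped += 1
                continue
            if reaction == "dimerization":
                kas.append(compute_ka_dimer(i_product, i_monomer))
            else:
                kas.append(
                    compute_ka_complex(i_product, i_monomer, tmao_concentration)
                )
        if not kas:
            logger.info(
                "temperature %.1f K excluded: product intensity zero in all replicates",
                temperature,
            )
            continue
        lnk = np.log(kas)
        inv_t.append(1.0 / temperature)
        if average == "log":
            ln_mean.append(float(np.mean(lnk)))
        else:
            ln_mean.append(float(np.log(np.mean(kas))))
        ln_sd.append(float(np.std(lnk, ddof=1)) if len(lnk) >= 2 else np.nan)
        n_rep.append(len(lnk))
    if n_dropped:
        logger.info("dropped %d zero-product replicate rows", n_dropped)
    if len(inv_t) < 2:
        raise ValueError("fewer than 2 usable temperatures after dropping")
    return VantHoffSeries(
        np.array(inv_t), np.array(ln_mean), np.array(ln_sd), np.array(n_rep)
    )


@dataclass
class RegimeFit:
    """OLS fit of ln Ka on 1/T over one temperature regime."""

    slope: float  # K
    intercept: float
    slope_sd: float
    intercept_sd: float
    temperature_range: tuple[float, float]  # K, (low, high)
    n_points: int = 0
    rss: float = 0.0


def fit_single_regime(
    series: VantHoffSeries,
    temperature_range: tuple[float, float] | None = None,
) -> RegimeFit:
    """Ordinary least squares of ln Ka on 1/T over a temperature window."""
    t = series.temperatures
    if temperature_range is None:
        mask = np.ones(len(series), dtype=bool)
        temperature_range = (float(t.min()), float(t.max()))
    else:
        lo, hi = temperature_range
        mask = (t >= lo) & (t <= hi)
    x = series.inverse_temperature[mask]
    y = series.ln_ka[mask]
    if len(x) < 2:
        raise ValueError("need at least 2 points in temperature range")
    if np.ptp(x) == 0:
        raise ValueError("singular design: all temperatures equal")
    res = stats.linregress(x, y)
    predicted = res.intercept + res.slope * x
    rss = float(np.sum((y - predicted) ** 2))
    return RegimeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_sd=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        intercept_sd=float(res.intercept_stderr)
        if np.isfinite(res.intercept_stderr)
        else 0.0,
        temperature_range=(float(temperature_range[0]), float(temperature_range[1])),
        n_points=int(len(x)),
        rss=rss,
    )


@dataclass
class TwoRegimeFit:
    """Segmented van't Hoff fit: one breakpoint, two OLS lines.

    The low regime covers temperatures <= breakpoint, the high regime
    temperatures > breakpoint. ``degenerate_flag`` is set when the two
    slopes are statistically indistinguishable.
    """

    breakpoint: float  # K
    low_regime: RegimeFit
    high_regime: RegimeFit
    degenerate_flag: bool = False
    candidate_rss: dict = field(default_factory=dict)

    @property
    def total_rss(self) -> float:
        return self.low_regime.rss + self.high_regime.rss


def fit_two_regime(
    series: VantHoffSeries,
    candidate_breakpoints="auto",
    min_points_per_side: int = 3,
) -> TwoRegimeFit:
    """Two-segment van't Hoff fit with RSS-minimizing breakpoint selection.

    Candidates are measured temperatures with at least ``min_points_per_side``
    points at or below and strictly above them. Ties in total RSS are broken
    toward the candidate closest to the median measured temperature. Pass an
    explicit list (possibly of length one) to fix the breakpoint.
    """
    t = series.temperatures
    if isinstance(candidate_breakpoints, str) and candidate_breakpoints == "auto":
        candidates = [
            float(bp)
            for bp in np.unique(t)
            if (t <= bp).sum() >= min_points_per_side
            and (t > bp).sum() >= min_points_per_side
        ]
    else:
        candidates = [float(b) for b in np.atleast_1d(candidate_breakpoints)]
        for bp in candidates:
            if (t <= bp).sum() < 2 or (t > bp).sum() < 2:
                raise ValueError(f"breakpoint {bp} K leaves a side with <2 points")
    if not candidates:
        raise ValueError("no admissible breakpoint")

    t_median = float(np.median(t))
    best: TwoRegimeFit | None = None
    rss_by_candidate: dict[float, float] = {}
    for bp in candidates:
        low = fit_single_regime(series, (float(t.min()), bp))
        high_lo = float(t[t > bp].min())
        high = fit_single_regime(series, (high_lo, float(t.max())))
        rss = low.rss + high.rss
        rss_by_candidate[bp] = rss
        fit = TwoRegimeFit(breakpoint=bp, low_regime=low, high_regime=high)
        if best is None:
            best = fit
            continue
        current = best.total_rss
        if rss < current - 1e-12 * max(1.0, current):
            best = fit
        elif abs(rss - current) <= 1e-12 * max(1.0, current, rss):
            if abs(bp - t_median) < abs(best.breakpoint - t_median):
                best = fit
    assert best is not None
    best.candidate_rss = rss_by_candidate

    slope_diff = abs(best.low_regime.slope - best.high_regime.slope)
    pooled_sd = math.hypot(best.low_regime.slope_sd, best.high_regime.slope_sd)
    scale = max(abs(best.low_regime.slope), abs(best.high_regime.slope), 1.0)
    best.degenerate_flag = slope_diff <= max(pooled_sd, 1e-9 * scale)
    return best


@dataclass
class ThermoQuantities:
    """Enthalpy, entropy, and Gibbs energy derived from a van't Hoff line.

    Invariants: dG_at_ref == dH + mTdS_at_ref and
    mTdS_at_ref == -reference_temperature * dS, both to machine precision.
    """

    dH: float  # kJ/mol
    dS: float  # kJ/mol/K
    mTdS_at_ref: float  # kJ/mol
    dG_at_ref: float  # kJ/mol
    reference_temperature: float  # K
    dH_sd: float = 0.0
    dS_sd: float = 0.0
    mTdS_sd: float = 0.0
    dG_sd: float = 0.0


def thermo_from_fit(fit: RegimeFit, reference_temperature: float) -> ThermoQuantities:
    """Convert a van't Hoff line into dH, dS, -T*dS, and dG at T_ref.

    dH = -R*slope and dS = R*intercept; uncertainties are propagated
    linearly from the slope/intercept standard errors (treated as
    independent, a deliberate simplification — replicate resampling is the
    primary uncertainty channel).
    """
    if not (np.isfinite(fit.slope) and np.isfinite(fit.intercept)):
        raise ValueError("fit has non-finite estimates")
    dH = -R_KJ * fit.slope
    dS = R_KJ * fit.intercept
    mTdS = -reference_temperature * dS
    dG = dH + mTdS
    dH_sd = R_KJ * fit.slope_sd
    dS_sd = R_KJ * fit.intercept_sd
    mTdS_sd = reference_temperature * dS_sd
    dG_sd = math.hypot(dH_sd, mTdS_sd)
    return ThermoQuantities(
        dH=dH,
        dS=dS,
        mTdS_at_ref=mTdS,
        dG_at_ref=dG,
        reference_temperature=reference_temperature,
        dH_sd=dH_sd,
        dS_sd=dS_sd,
        mTdS_sd=mTdS_sd,
        dG_sd=dG_sd,
    )


def gibbs_from_components(dH: float, mTdS: float) -> float:
    """dG = dH + (-T*dS), both terms in kJ/mol at a common temperature."""
    return dH + mTdS


def replicate_uncertainty(
    fits: list[RegimeFit], reference_temperature: float
) -> dict[str, float]:
    """Sample sd of each derived quantity across replicate-resampled fits."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits")
    quantities = [thermo_from_fit(f, reference_temperature) for f in fits]
    out = {}
    for name in ("dH", "dS", "mTdS_at_ref", "dG_at_ref"):
        values = np.array([getattr(q, name) for q in quantities])
        out[name] = float(np.std(values, ddof=1))
    return out


def fit_per_replicate(
    table: pd.DataFrame,
    reaction: str = "dimerization",
    tmao_concentration: float | None = None,
    temperature_range: tuple[float, float] | None = None,
) -> list[RegimeFit]:
    """One single-regime fit per replicate id (for replicate_uncertainty)."""
    fits = []
    for _, sub in table.groupby("replicate"):
        series = build_vant_hoff_series(
            sub.reset_index(drop=True), reaction, tmao_concentration
        )
        fits.append(fit_single_regime(series, temperature_range))
    return fits


def thermo_report(
    two_regime: TwoRegimeFit, reference_temperature: float, reaction: str
) -> pd.DataFrame:
    """Flatten a two-regime fit into the report-CSV schema."""
    rows = []
    for regime_name, fit in (
        ("low", two_regime.low_regime),
        ("high", two_regime.high_regime),
    ):
        q = thermo_from_fit(fit, reference_temperature)
        rows.append(
            {
                "reaction": reaction,
                "regime": regime_name,
                "breakpoint_K": two_regime.breakpoint,
                "dH_kJmol": q.dH,
                "dH_sd": q.dH_sd,
                "mTdS_kJmol": q.mTdS_at_ref,
                "mTdS_sd": q.mTdS_sd,
                "dG_kJmol": q.dG_at_ref,
                "dG_sd": q.dG_sd,
                "T_ref_K": reference_temperature,
            }
        )
    return pd.DataFrame(rows)
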