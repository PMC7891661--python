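"""Taurine/DFAA release rates from crustacean-zooplankton incubations.

A known number of specimens sits in a jar of 0.2 µm filtered seawater and the
dissolved analyte concentrations are followed over a few hours. The analyte
accumulates roughly linearly until release stalls (a plateau); an OLS slope
over the pre-plateau window, quality-filtered on R² and p, gives the release
rate, which is then normalized per individual and per unit carbon biomass
(ellipsoid biovolume × 0.08 pg C µm⁻³) and scaled by in-situ copepod
abundance to a bulk water-column release and turnover rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import CARBON_PER_BIOVOLUME_PG_UM3

__all__ = [
    "IncubationExperiment",
    "ReleaseRate",
    "BulkRelease",
    "ellipsoid_biovolume",
    "carbon_biomass",
    "specimen_carbon_biomass_g",
    "plateau_cutoff",
    "fit_release_slope",
    "normalize_release",
    "bulk_release_and_turnover",
    "analyze_experiment",
    "read_incubation_csv",
    "read_specimen_csv",
]

#: QC thresholds for accepting a regression slope as a release rate.
QC_MIN_R_SQUARED = 0.60
QC_MAX_P_VALUE = 0.05


@dataclass
class IncubationExperiment:
    """Time-resolved analyte concentrations in incubation jars.

    ``concentrations`` maps analyte -> array of shape (n_replicates, n_times)
    in nmol L⁻¹; ``control_concentrations`` has the same layout for the
    zero-specimen control jars (may be empty).
    """

    times_h: np.ndarray
    concentrations: dict[str, np.ndarray]
    control_concentrations: dict[str, np.ndarray]
    n_individuals: int
    jar_volume_l: float
    specimens: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.times_h.ndim != 1 or len(self.times_h) < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.jar_volume_l <= 0:
            raise ValueError("jar volume must be positive")
        if self.n_individuals < 1:
            raise ValueError("need at least one specimen")
        for analyte, arr in self.concentrations.items():
            arr = np.atleast_2d(np.asarray(arr, dtype=float))
            if arr.shape[1] != len(self.times_h):
                raise ValueError(f"{analyte}: concentration/time shape mismatch")
            if np.any(arr < 0):
                raise ValueError(f"{analyte}: negative concentration")
            self.concentrations[analyte] = arr

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations)

    @property
    def n_replicates(self) -> int:
        return next(iter(self.concentrations.values())).shape[0]


@dataclass
class ReleaseRate:
    """A QC-filtered release-rate estimate for one analyte and jar."""

    analyte: str
    replicate: int
    slope_nmol_l_h: float
    r_squared: float
    p_value: float
    qc_pass: bool
    window_end_h: float
    per_individual_nmol_d: float | None = None
    per_biomass_umol_g_d: float | None = None


@dataclass
class BulkRelease:
    """In-situ bulk release scaled by animal abundance, with turnover."""

    rate_nmol_l_d: float
    copepod_abundance_ind_l: float
    mean_concentration_nmol_l: float | None
    turnover_per_d: float | None


def ellipsoid_biovolume(prosome_length_um: float, prosome_diameter_um: float) -> float:
    """Ellipsoid biovolume of a copepod prosome, µm³.

    V = (4/3)·π·a·b² with a = length/2 and b = diameter/2. Accepts scalars
    or arrays.
    """
    length = np.asarray(prosome_length_um, dtype=float)
    diameter = np.asarray(prosome_diameter_um, dtype=float)
    if np.any(length <= 0) or np.any(diameter <= 0):
        raise ValueError("prosome length and diameter must be positive")
    vol = (4.0 / 3.0) * np.pi * (length / 2.0) * (diameter / 2.0) ** 2
    return float(vol) if vol.ndim == 0 else vol


def carbon_biomass(biovolume_um3: float) -> float:
    """Carbon biomass (pg C) from biovolume (µm³) at 0.08 pg C µm⁻³."""
    biovolume = np.asarray(biovolume_um3, dtype=float)
    if np.any(biovolume < 0):
        raise ValueError("biovolume must be non-negative")
    mass = CARBON_PER_BIOVOLUME_PG_UM3 * biovolume
    return float(mass) if mass.ndim == 0 else mass


def specimen_carbon_biomass_g(specimens: pd.DataFrame) -> float:
    """Total carbon biomass (g C) of a specimen table.

    Expects columns ``length_um`` and ``diameter_um``; sums individual
    ellipsoid biomasses (1 pg = 1e-12 g).
    """
    volumes = ellipsoid_biovolume(
        specimens["length_um"].to_numpy(), specimens["diameter_um"].to_numpy()
    )
    return float(np.sum(carbon_biomass(volumes))) * 1e-12


def plateau_cutoff(
    times_h: np.ndarray,
    concentrations: dict[str, np.ndarray],
    tol: float = 0.0,
) -> float:
    """Earliest time at which any monitored analyte stops increasing.

    Scans consecutive time points of the replicate-mean series of every
    analyte; when a point fails to exceed the previous one by more than
    ``tol``·previous, release has stalled and the regression window ends at
    the previous (last still-increasing) time point. A series flat from 2 h
    onward therefore gives a 2 h window. Returns the last time point if
    every analyte keeps increasing throughout.
    """
    times = np.asarray(times_h, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least three time points to locate a plateau")
    cutoff_idx = len(times) - 1
    for arr in concentrations.values():
        series = np.atleast_2d(np.asarray(arr, dtype=float)).mean(axis=0)
        for i in range(1, len(times)):
            if series[i] <= series[i - 1] * (1.0 + tol):
                cutoff_idx = min(cutoff_idx, i - 1)
                break
    return float(times[cutoff_idx])


def fit_release_slope(times_h: np.ndarray, concentrations_nmol_l: np.ndarray):
    """OLS slope of concentration on time with QC flags.

    Returns ``(slope, r_squared, p_value, qc_pass)``. The p-value is the
    standard two-sided t test for slope = 0 with n−2 degrees of freedom;
    QC passes when R² ≥ 0.60 and p ≤ 0.05.
    """
    t = np.asarray(times_h, dtype=float)
    c = np.asarray(concentrations_nmol_l, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least three points for regression")
    if np.ptp(t) == 0:
        raise ValueError("zero variance in time")
    if np.ptp(c) == 0:
        # constant series: slope 0, no explainable variance
        return 0.0, 0.0, 1.0, False
    res = stats.linregress(t, c)
    r2 = res.rvalue**2
    p = res.pvalue
    qc = bool(r2 >= QC_MIN_R_SQUARED and p <= QC_MAX_P_VALUE)
    return float(res.slope), float(r2), float(p), qc


def normalize_release(
    slope_nmol_l_h: float,
    jar_volume_l: float,
    n_individuals: int,
    total_biomass_g_c: float,
) -> tuple[float, float]:
    """Per-individual and per-carbon-biomass release rates.

    per_individual = slope·V·24/n                 [nmol individual⁻¹ d⁻¹]
    per_biomass    = slope·V·24/(biomass·10³)     [µmol (g C)⁻¹ d⁻¹]
    """
    if jar_volume_l <= 0:
        raise ValueError("jar volume must be positive")
    if n_individuals <= 0:
        raise ValueError("need at least one individual")
    if total_biomass_g_c <= 0:
        raise ValueError("biomass must be positive")
    daily = slope_nmol_l_h * jar_volume_l * 24.0
    per_individual = daily / n_individuals
    per_biomass = daily / (total_biomass_g_c * 1e3)
    return per_individual, per_biomass


def bulk_release_and_turnover(
    per_individual_nmol_d: float,
    abundance_ind_l: float,
    mean_concentration_nmol_l: float | None = None,
) -> BulkRelease:
    """Scale a per-individual release to in-situ bulk release and turnover.

    rate = per_individual × abundance; turnover = rate / mean concentration.
    Turnover is None (flagged undefined) when no positive mean concentration
    is supplied, except that zero abundance gives turnover 0.
    """
    if abundance_ind_l < 0:
        raise ValueError("abundance must be non-negative")
    rate = per_individual_nmol_d * abundance_ind_l
    turnover: float | None
    if abundance_ind_l == 0:
        turnover = 0.0
    elif mean_concentration_nmol_l is not None and mean_concentration_nmol_l > 0:
        turnover = rate / mean_concentration_nmol_l
    else:
        turnover = None
    return BulkRelease(
        rate_nmol_l_d=rate,
        copepod_abundance_ind_l=abundance_ind_l,
        mean_concentration_nmol_l=mean_concentration_nmol_l,
        turnover_per_d=turnover,
    )


def _control_drift_slope(times: np.ndarray, control: np.ndarray) -> float:
    """Slope of the control series if it drifts significantly, else 0.

    Controls contain no animals, so any significant trend (p ≤ 0.05) is
    analytical drift and is subtracted from the jar slopes.
    """
    series = np.atleast_2d(control).mean(axis=0)
    if np.ptp(series) == 0:
        return 0.0
    res = stats.linregress(times, series)
    return float(res.slope) if res.pvalue <= 0.05 else 0.0


def analyze_experiment(
    experiment: IncubationExperiment,
    tol: float = 0.0,
    pool_replicates: bool = False,
    subtract_control_drift: bool = True,
) -> list[ReleaseRate]:
    """Full release-rate estimation for one incubation experiment.

    Locates the plateau window shared by all analytes, fits each replicate
    jar independently (or pools all points when ``pool_replicates``),
    optionally subtracts significant control drift, applies the R²/p QC
    filter, and attaches per-individual and per-biomass normalizations to
    passing fits.
    """
    cutoff = plateau_cutoff(experiment.times_h, experiment.concentrations, tol=tol)
    # regression needs at least three points; never shrink the window below that
    cutoff = max(cutoff, float(experiment.times_h[2]))
    mask = experiment.times_h <= cutoff
    times = experiment.times_h[mask]

    biomass_g = (
        specimen_carbon_biomass_g(experiment.specimens)
        if experiment.specimens is not None and len(experiment.specimens)
        else None
    )

    results: list[ReleaseRate] = []
    for analyte, arr in experiment.concentrations.items():
        drift = 0.0
        control = experiment.control_concentrations.get(analyte)
        if subtract_control_drift and control is not None and np.size(control):
            drift = _control_drift_slope(times, np.atleast_2d(control)[:, mask])

        if pool_replicates:
            jobs = [(-1, np.repeat(times, arr.shape[0]), arr[:, mask].T.ravel())]
        else:
            jobs = [(rep, times, arr[rep, mask]) for rep in range(arr.shape[0])]

        for rep, t, c in jobs:
            slope, r2, p, qc = fit_release_slope(t, c)
            slope -= drift
            rate = ReleaseRate(
                analyte=analyte,
                replicate=rep,
                slope_nmol_l_h=slope,
                r_squared=r2,
                p_value=p,
                qc_pass=qc,
                window_end_h=cutoff,
            )
            if qc:
                per_ind, per_bio = normalize_release(
                    slope,
                    experiment.jar_volume_l,
                    experiment.n_individuals,
                    biomass_g if biomass_g else math.inf,
                )
                rate.per_individual_nmol_d = per_ind
                rate.per_biomass_umol_g_d = per_bio if biomass_g else None
            results.append(rate)
    return results


def summarize_release(rates: list[ReleaseRate]) -> pd.DataFrame:
    """Mean ± SD of QC-passing per-individual rates, per analyte."""
    rows = []
    for analyte in sorted({r.analyte for r in rates}):
        ok = [r for r in rates if r.analyte == analyte and r.qc_pass]
        vals = [r.per_individual_nmol_d for r in ok if r.per_individual_nmol_d is not None]
        rows.append(
            {
                "analyte": analyte,
                "n_pass": len(ok),
                "n_total": sum(r.analyte == analyte for r in rates),
                "per_individual_mean": float(np.mean(vals)) if vals else np.nan,
                "per_individual_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def read_incubation_csv(
    path,
    n_individuals: int,
    jar_volume_l: float = 0.5,
    specimens: pd.DataFrame | None = None,
) -> IncubationExperiment:
    """Load an incubation table.

    Columns: ``time_h, analyte, replicate, conc_nmol_L, is_control``.
    """
    df = pd.read_csv(path)
    times = np.sort(df["time_h"].unique())
    conc: dict[str, np.ndarray] = {}
    ctrl: dict[str, np.ndarray] = {}
    for (analyte, is_control), grp in df.groupby(["analyte", "is_control"]):
        wide = grp.pivot_table(index="replicate", columns="time_h", values="conc_nmol_L")
        arr = wide.reindex(columns=times).to_numpy()
        (ctrl if is_control else conc)[analyte] = arr
    return IncubationExperiment(
        times_h=times,
        concentrations=conc,
        control_concentrations=ctrl,
        n_individuals=n_individuals,
        jar_volume_l=jar_volume_l,
        specimens=specimens,
    )


def read_specimen_csv(path) -> pd.DataFrame:
    """Load a specimen morphometry table (columns length_um, diameter_um)."""
    df = pd.read_csv(path)
    if not {"length_um", "diameter_um"} <= set(df.columns):
        raise ValueError("specimen CSV needs length_um and diameter_um columns")
    return df
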