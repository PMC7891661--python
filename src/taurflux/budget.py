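"""Taurine-C/N/S contributions to prokaryotic requirements and budget closure.

Taurine (C₂H₇NO₃S) delivers 2 C, 1 N and 1 S atoms per molecule. Its
assimilation rate converts to a carbon flux via 2 × 12.011 g mol⁻¹; dividing
by the leucine-derived biomass production gives the taurine-C share of the
carbon demand. The N and S shares follow from the bacterial atomic ratios
C:N = 4:1 and C:S = 26:1: with the default constants,
N share = 2 × C share and S share = 13 × C share, exactly.

The supply side of the budget is the copepod bulk release rate; the demand
side is the prokaryotic bulk uptake. Their ratio says whether zooplankton
alone can sustain the community's taurine consumption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_STOICHIOMETRY, StoichiometryConstants
from .tracer import leucine_to_biomass_production

__all__ = [
    "ElementalBudget",
    "taurine_carbon_flux",
    "contribution_to_requirements",
    "supply_demand",
    "StoichiometryConstants",
]


@dataclass
class ElementalBudget:
    """Taurine contributions (%) to C/N/S requirements plus budget closure."""

    c_contribution_pct: float | None
    n_contribution_pct: float | None
    s_contribution_pct: float | None
    supply_nmol_l_d: float | None = None
    demand_nmol_l_d: float | None = None
    coverage_ratio: float | None = None

    @property
    def covered(self) -> bool | None:
        if self.coverage_ratio is None:
            return None
        return self.coverage_ratio >= 1.0


def taurine_carbon_flux(
    assimilation_nmol_l_d: float,
    constants: StoichiometryConstants = DEFAULT_STOICHIOMETRY,
) -> float:
    """Taurine-derived carbon flux, µg C L⁻¹ d⁻¹.

    flux = assimilation × (C atoms per taurine) × molar mass of C × 10⁻³
    (nmol L⁻¹ d⁻¹ × g mol⁻¹ → µg C L⁻¹ d⁻¹).
    """
    if assimilation_nmol_l_d < 0:
        raise ValueError("assimilation must be non-negative")
    return assimilation_nmol_l_d * constants.taurine_c * constants.molar_mass_c * 1e-3


def contribution_to_requirements(
    taurine_assimilation_nmol_l_d: float,
    biomass_production_ugc_l_d: float,
    constants: StoichiometryConstants = DEFAULT_STOICHIOMETRY,
) -> ElementalBudget:
    """Taurine-C/N/S shares of the prokaryotic C/N/S requirements, percent.

    C share  = 100 × taurine-C flux / biomass production;
    N share  = C share × (N:C of taurine) × (C:N of cells);
    S share  = C share × (S:C of taurine) × (C:S of cells).
    """
    if biomass_production_ugc_l_d <= 0:
        return ElementalBudget(None, None, None)
    c = 100.0 * taurine_carbon_flux(taurine_assimilation_nmol_l_d, constants) \
        / biomass_production_ugc_l_d
    n = c * (constants.taurine_n / constants.taurine_c) * constants.cell_c_to_n
    s = c * (constants.taurine_s / constants.taurine_c) * constants.cell_c_to_s
    return ElementalBudget(c, n, s)


def contributions_from_c(
    c_contribution_pct: float,
    constants: StoichiometryConstants = DEFAULT_STOICHIOMETRY,
) -> tuple[float, float]:
    """N and S contributions implied by a given C contribution (all %)."""
    n = c_contribution_pct * (constants.taurine_n / constants.taurine_c) \
        * constants.cell_c_to_n
    s = c_contribution_pct * (constants.taurine_s / constants.taurine_c) \
        * constants.cell_c_to_s
    return n, s


def contribution_from_leucine(
    taurine_assimilation_nmol_l_d: float,
    leucine_incorporation_nmol_l_d: float,
    constants: StoichiometryConstants = DEFAULT_STOICHIOMETRY,
) -> ElementalBudget:
    """Contributions with biomass production derived from leucine uptake."""
    bp = leucine_to_biomass_production(leucine_incorporation_nmol_l_d)
    return contribution_to_requirements(
        taurine_assimilation_nmol_l_d, bp, constants
    )


def supply_demand(
    bulk_release_nmol_l_d: float, bulk_uptake_nmol_l_d: float
) -> ElementalBudget:
    """Zooplankton supply vs prokaryotic demand closure.

    coverage_ratio = release / uptake; the supply covers the demand when the
    ratio is at least 1.
    """
    if bulk_uptake_nmol_l_d <= 0:
        raise ValueError("bulk uptake must be positive")
    if bulk_release_nmol_l_d < 0:
        raise ValueError("bulk release must be non-negative")
    ratio = bulk_release_nmol_l_d / bulk_uptake_nmol_l_d
    return ElementalBudget(
        None, None, None,
        supply_nmol_l_d=bulk_release_nmol_l_d,
        demand_nmol_l_d=bulk_uptake_nmol_l_d,
        coverage_ratio=ratio,
    )


def mean_of_ratios(numerators, denominators) -> float:
    """Seasonal summary as the mean of per-sample ratios (not ratio of means)."""
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if num.shape != den.shape:
        raise ValueError("arrays must match in length")
    if np.any(den <= 0):
        raise ValueError("denominators must be positive")
    return float(np.mean(num / den))
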