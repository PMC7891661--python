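"""Physical and biogeochemical constants shared across the pipeline.

All radioactivity bookkeeping is done in DPM (disintegrations per minute,
already counter-efficiency corrected by definition). Specific activities are
carried in Ci mmol⁻¹ so that taurine (mCi-range) and leucine (Ci-range)
tracers share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Disintegrations per minute in one curie.
DPM_PER_CI: float = 2.22e12

#: Carbon volume-to-mass conversion for crustacean zooplankton, pg C per µm³.
CARBON_PER_BIOVOLUME_PG_UM3: float = 0.08

#: Theoretical leucine-to-carbon conversion, kg C per mol leucine.
#: Numerically equal to µg C per nmol leucine.
LEUCINE_CARBON_KG_PER_MOL: float = 1.55

#: Specific activity of the ¹⁴C-taurine tracer, Ci mmol⁻¹ (60 mCi mmol⁻¹).
TAURINE_14C_SPECIFIC_ACTIVITY_CI_MMOL: float = 0.060

#: Specific activity of the ³H-leucine tracer, Ci mmol⁻¹.
LEUCINE_3H_SPECIFIC_ACTIVITY_CI_MMOL: float = 120.0

#: Molar mass of carbon, g mol⁻¹.
MOLAR_MASS_C: float = 12.011


def dpm_per_nmol(specific_activity_ci_mmol: float) -> float:
    """DPM carried by one nmol of tracer at the given specific activity.

    1 Ci mmol⁻¹ = 2.22e12 DPM mmol⁻¹ = 2.22e6 DPM nmol⁻¹.
    """
    if specific_activity_ci_mmol <= 0:
        raise ValueError("specific activity must be positive")
    return specific_activity_ci_mmol * DPM_PER_CI / 1e6


@dataclass(frozen=True)
class StoichiometryConstants:
    """Elemental composition of taurine and bacterial cell stoichiometry.

    Taurine is C₂H₇NO₃S: 2 C, 1 N and 1 S atoms per molecule. Bacterial
    elemental ratios follow the Fagerbakke-type atomic ratios C:N = 4:1 and
    C:S = 26:1.
    """

    taurine_c: int = 2
    taurine_n: int = 1
    taurine_s: int = 1
    cell_c_to_n: float = 4.0
    cell_c_to_s: float = 26.0
    molar_mass_c: float = MOLAR_MASS_C

    def __post_init__(self) -> None:
        for name in ("taurine_c", "taurine_n", "taurine_s",
                     "cell_c_to_n", "cell_c_to_s", "molar_mass_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_STOICHIOMETRY = StoichiometryConstants()
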