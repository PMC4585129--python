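"""Energetics of sulfate-coupled anaerobic methane oxidation (AOM).

The net catabolic reaction considered throughout is

    CH4 + SO4^2-  ->  CO2 (as total CO2) + HS- (+ H2O)

with 1:1:1:1 stoichiometry, so the reaction quotient

    Q = ([CO2][HS-]) / ([CH4][SO4^2-])

is dimensionless and millimolar concentrations can be used directly.  The
in-situ Gibbs energy is the standard transformed value corrected for actual
concentrations,

    dG' = dG0' + R*T*ln(Q)      [kJ per mol CH4]

with dG0' = -21 kJ/mol (methane as a gas, products CO2 and HS-).  Activities
are taken equal to molar concentrations (coefficients 1, water activity 1)
and total dissolved sulfide is treated entirely as HS- (medium pH 7.2-7.5);
no carbonate/sulfide speciation and no ionic-strength corrections are
applied.  The temperature entering R*T defaults to 293.15 K, the reference
temperature of the methane solubility anchor (1.31 mM at salinity 30,
20 degC); the 15 degC incubation temperature can be passed instead.

Computed dG' values are compared with bioenergetic cutoffs: roughly
-19 kJ/mol CH4 for growth-permissive conditions, -10.6 kJ/mol for bare
maintenance (one proton translocation, the biological energy quantum), and
-10 kJ/mol as the estimate for ANME/SRB aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT_KJ",
    "IncubationCondition",
    "ThermoParams",
    "EnergyThresholds",
    "SolubilityParams",
    "UndefinedQuotientError",
    "reaction_quotient",
    "delta_g_prime",
    "classify_energetic_regime",
    "dissolved_methane",
    "REGIMES",
    "TABLE1_CONDITIONS",
]

#: Gas constant in kJ mol^-1 K^-1.
GAS_CONSTANT_KJ = 0.0083145


class UndefinedQuotientError(ValueError):
    """The reaction quotient is undefined (a reactant concentration is zero)."""


@dataclass(frozen=True)
class IncubationCondition:
    """Average concentrations defining one experimental condition.

    All concentrations are in mM.  ``methane_mM`` is the dissolved methane
    concentration (the saturation value 1.31 mM whenever methane headspace
    is present); ``co2_mM`` is total CO2 as tabulated.  ``methane_added``
    flags whether the headspace carried methane, which decides whether an
    energy value is reported for the condition at all.
    """

    id: str
    sulfate_mM: float
    sulfide_mM: float
    methane_mM: float
    co2_mM: float
    methane_added: bool = True

    def __post_init__(self) -> None:
        for name in ("sulfate_mM", "sulfide_mM", "methane_mM", "co2_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class ThermoParams:
    """Constants entering dG' = dG0' + R*T*ln(Q)."""

    delta_g0_prime_kj: float = -21.0
    temperature_K: float = 293.15
    gas_constant_kj: float = GAS_CONSTANT_KJ

    def __post_init__(self) -> None:
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")


@dataclass(frozen=True)
class EnergyThresholds:
    """Bioenergetic cutoffs on the signed kJ/mol CH4 scale (more negative
    = more energy available).

    ``growth_threshold_kj`` separates growth-permissive from
    maintenance-only conditions; ``maintenance_threshold_kj`` is the
    minimum biological energy quantum; ``aggregate_threshold_kj`` is the
    literature estimate for ANME/SRB aggregates (stored for reference,
    not used by the classifier).
    """

    growth_threshold_kj: float = -19.0
    maintenance_threshold_kj: float = -10.6
    aggregate_threshold_kj: float = -10.0

    def __post_init__(self) -> None:
        # growth cutoff must be the more negative (signed scale)
        if self.growth_threshold_kj > self.maintenance_threshold_kj:
            raise ValueError(
                "growth_threshold_kj must be <= maintenance_threshold_kj "
                "on the signed scale"
            )


@dataclass(frozen=True)
class SolubilityParams:
    """Dissolved-methane anchor: 1.31 mM at salinity 30 and 20 degC."""

    ch4_sat_mM: float = 1.31
    salinity: float = 30.0
    reference_temp_C: float = 20.0
    neglect_overpressure: bool = True

    def __post_init__(self) -> None:
        if self.ch4_sat_mM <= 0:
            raise ValueError("ch4_sat_mM must be positive")


#: Ordered from most to least energetically permissive.
REGIMES = ("growth_permissive", "maintenance_only", "below_quantum")


def reaction_quotient(cond: IncubationCondition) -> float:
    """Return Q = ([CO2][HS-]) / ([CH4][SO4^2-]) for a condition.

    Scale-invariant: multiplying all four concentrations by a common
    factor leaves Q unchanged (1:1:1:1 stoichiometry).

    Raises
    ------
    UndefinedQuotientError
        If methane or sulfate concentration is zero, naming the species.
    """
    zeros = [
        name
        for name, value in (
            ("methane", cond.methane_mM),
            ("sulfate", cond.sulfate_mM),
        )
        if value == 0
    ]
    if zeros:
        raise UndefinedQuotientError(
            f"reaction quotient undefined for condition {cond.id!r}: "
            f"zero concentration of {' and '.join(zeros)}"
        )
    return (cond.co2_mM * cond.sulfide_mM) / (cond.methane_mM * cond.sulfate_mM)


def delta_g_prime(
    cond: IncubationCondition, params: ThermoParams = ThermoParams()
) -> float:
    """In-situ Gibbs energy dG' = dG0' + R*T*ln(Q), kJ per mol CH4.

    Propagates :class:`UndefinedQuotientError` when Q is undefined.  Note
    ln(Q) diverges to -inf as products vanish; zero sulfide or CO2 yields
    ``-inf`` rather than an error (thermodynamically meaningful limit).
    """
    q = reaction_quotient(cond)
    rt = params.gas_constant_kj * params.temperature_K
    if q == 0:
        return -math.inf
    return params.delta_g0_prime_kj + rt * math.log(q)


def classify_energetic_regime(
    dg: float, thresholds: EnergyThresholds = EnergyThresholds()
) -> str:
    """Classify a dG' value against the bioenergetic cutoffs.

    Boundary ties go to the more permissive class (<=): a condition at
    exactly the growth cutoff counts as growth-permissive, matching the
    treatment of the methane-only condition at -19.2 kJ/mol as active.
    """
    if math.isnan(dg):
        raise ValueError("dg must be a finite (or -inf) energy, got NaN")
    if dg <= thresholds.growth_threshold_kj:
        return "growth_permissive"
    if dg <= thresholds.maintenance_threshold_kj:
        return "maintenance_only"
    return "below_quantum"


def dissolved_methane(
    sol: SolubilityParams = SolubilityParams(), headspace_bar: float = 1.8
) -> float:
    """Dissolved CH4 concentration (mM) under a given headspace pressure.

    With ``neglect_overpressure`` (the default, and the assumption behind
    the tabulated 1.31 mM) the saturation value is returned unchanged.
    Setting it false enables a simple linear Henry scaling with pressure
    relative to 1 bar — an extension beyond the tabulated treatment.
    """
    if headspace_bar < 0:
        raise ValueError("headspace pressure must be >= 0 bar")
    if sol.neglect_overpressure:
        return sol.ch4_sat_mM
    return sol.ch4_sat_mM * headspace_bar


# The seven-condition roster (average concentrations over the 947-day run).
# Conditions 5 and 7 had no methane headspace; dissolved methane is recorded
# as 0 and no energy value is defined for them.
TABLE1_CONDITIONS: tuple[IncubationCondition, ...] = (
    IncubationCondition("1_CH4_highSO4", 21.6, 0.4, 1.31, 3.8, True),
    IncubationCondition("2_CH4_highSO4_highS", 21.1, 3.8, 1.31, 6.9, True),
    IncubationCondition("3_CH4_lowSO4", 3.6, 0.4, 1.31, 4.4, True),
    IncubationCondition("4_CH4_lowSO4_highS", 4.0, 3.6, 1.31, 6.4, True),
    IncubationCondition("5_highSO4", 21.6, 0.2, 0.0, 3.2, False),
    IncubationCondition("6_CH4_only", 0.1, 0.1, 1.31, 2.7, True),
    IncubationCondition("7_highS", 0.4, 3.0, 0.0, 4.4, False),
)
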