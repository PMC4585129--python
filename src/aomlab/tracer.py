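"""Headspace gas bookkeeping and 13C-isotopologue accounting.

Serum-bottle incubations (244 mL total, 120 mL slurry, 1.8 bar headspace,
15 degC) are tracked as per-bottle amounts.  Gas measurements are reduced
to a two-isotopologue representation per species (12C and 13C amounts of
CH4 and CO2); raw mass-spectral channel math is out of scope, so the
amounts are taken as given.

The activity readout mirrors the tracer experiment: after 13CH4 addition
on day 540, the 13C fraction of the CO2 pool rises wherever methane is
oxidized.  ``percent_13co2`` anchors that fraction at the label-addition
time point, so produced 13CO2 (%) is zero at the anchor by construction
and insensitive to the natural-abundance baseline.  Total methane oxidized
is back-estimated by dividing produced 13CO2 by the 13C fraction of the
methane pool (label dilution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "GAS_CONSTANT_L_BAR",
    "BottleSpec",
    "IsotopologueReading",
    "LabelState",
    "headspace_amount",
    "isotope_fraction",
    "percent_13co2",
    "methane_oxidized",
]

#: Gas constant in L bar mol^-1 K^-1.
GAS_CONSTANT_L_BAR = 0.0831446


@dataclass(frozen=True)
class BottleSpec:
    """Geometry and physical state of one serum bottle."""

    total_volume_L: float = 0.244
    liquid_volume_L: float = 0.120  # 30 mL sediment + 90 mL medium
    headspace_pressure_bar: float = 1.8
    temperature_K: float = 288.15  # 15 degC incubation

    def __post_init__(self) -> None:
        if not self.liquid_volume_L < self.total_volume_L:
            raise ValueError("liquid volume must be smaller than total volume")

    @property
    def headspace_volume_L(self) -> float:
        return self.total_volume_L - self.liquid_volume_L


@dataclass(frozen=True)
class IsotopologueReading:
    """Amounts (mmol) of the 12C and 13C isotopologues of one species."""

    species: str  # "CO2" or "CH4"
    amount_12: float
    amount_13: float
    time_days: float

    def __post_init__(self) -> None:
        if self.species not in ("CO2", "CH4"):
            raise ValueError(f"species must be CO2 or CH4, got {self.species!r}")
        if self.amount_12 < 0 or self.amount_13 < 0:
            raise ValueError("isotopologue amounts must be >= 0")

    @property
    def total(self) -> float:
        return self.amount_12 + self.amount_13


@dataclass(frozen=True)
class LabelState:
    """13CH4 labeling scheme.

    ``f13_ch4`` is the 13C fraction of the headspace methane after label
    addition.  The default 0.12 follows from topping CH4 up to 1.6 bar and
    adding 99.99% 13CH4 to 1.8 bar: (0.2*1.0 + 1.6*0.011)/1.8 ~ 0.121.
    """

    label_start_day: float = 540.0
    f13_ch4: float = 0.12
    natural_abundance: float = 0.011

    def __post_init__(self) -> None:
        if not 0.0 <= self.f13_ch4 <= 1.0:
            raise ValueError("f13_ch4 must lie in [0, 1]")
        if not 0.0 <= self.natural_abundance <= 0.02:
            raise ValueError("natural_abundance must lie in [0, 0.02]")


def headspace_amount(spec: BottleSpec, partial_pressure_bar: float) -> float:
    """Ideal-gas amount n = P*V_headspace / (R*T) in mmol."""
    if partial_pressure_bar < 0:
        raise ValueError("partial pressure must be >= 0 bar")
    n_mol = (
        partial_pressure_bar
        * spec.headspace_volume_L
        / (GAS_CONSTANT_L_BAR * spec.temperature_K)
    )
    return n_mol * 1e3


def isotope_fraction(
    reading: IsotopologueReading,
    correct_natural: bool = False,
    natural_abundance: float = 0.011,
) -> float:
    """13C fraction of a reading, optionally natural-abundance corrected.

    The raw fraction is amount_13 / (amount_12 + amount_13).  With
    ``correct_natural`` the natural abundance is subtracted and the result
    clamped to [0, 1].
    """
    total = reading.total
    if total == 0:
        raise ValueError(
            f"isotope fraction undefined: zero total {reading.species} "
            f"at day {reading.time_days}"
        )
    frac = reading.amount_13 / total
    if correct_natural:
        frac = min(1.0, max(0.0, frac - natural_abundance))
    return frac


def percent_13co2(
    series: Sequence[IsotopologueReading], label: LabelState = LabelState()
) -> pd.DataFrame:
    """Produced 13CO2 (%) per time point, anchored at the label start.

    For every reading at day >= ``label.label_start_day`` the value is
    100 * (f13(t) - f13(baseline)), where the baseline is the latest
    reading at or before the label start.  The anchor point itself maps to
    0% by construction, and adding a constant to all fractions leaves the
    output unchanged.

    Returns a DataFrame with columns ``day`` and ``pct_13co2``.
    """
    readings = list(series)
    if any(r.species != "CO2" for r in readings):
        raise ValueError("percent_13co2 expects CO2 readings only")
    days = [r.time_days for r in readings]
    if days != sorted(days):
        raise ValueError("series must be sorted by time")
    baseline_candidates = [r for r in readings if r.time_days <= label.label_start_day]
    if not baseline_candidates:
        raise ValueError(
            f"no baseline CO2 reading at or before label start day "
            f"{label.label_start_day}"
        )
    f0 = isotope_fraction(baseline_candidates[-1])
    rows = [
        (r.time_days, 100.0 * (isotope_fraction(r) - f0))
        for r in readings
        if r.time_days >= label.label_start_day
    ]
    return pd.DataFrame(rows, columns=["day", "pct_13co2"])


def methane_oxidized(delta_13co2_mmol: float, f13_ch4: float) -> float:
    """Label-dilution estimate of methane oxidized (mmol).

    Divides the produced 13CO2 amount by the 13C fraction of the methane
    pool it was drawn from.
    """
    if f13_ch4 <= 0 or f13_ch4 > 1:
        raise ValueError("f13_ch4 must lie in (0, 1]")
    return delta_13co2_mmol / f13_ch4
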