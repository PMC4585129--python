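"""Seeded generator of a full synthetic incubation study.

Emulates the structure of a long-term (947 day) batch experiment: seven
conditions in biological triplicate, each a 244 mL serum bottle with
120 mL sediment slurry, crossing low/high sulfate with low/high sulfide
under a methane headspace plus methane-only, sulfate-only and
sulfide-only controls.

Mechanistic skeleton (forward Euler, 1 day steps):

* AOM rate = vmax * [SO4]/(Km + [SO4]) * gate, where the gate opens when
  the in-situ Gibbs energy dG' is at or below a critical value (default
  -19 kJ/mol CH4).  The hard step gate is the default; a smooth logistic
  variant is available as configuration.
* 1:1:1 CH4 : SO4 : HS- stoichiometry, tracked exactly in the noiseless
  ledger: sulfate falls, sulfide rises, headspace CH4 is converted to
  CO2 carrying the current 13C fraction of the methane pool.
* 13CH4 label added on day 540 to methane bottles (13C fraction 0.12).
* The methane-only condition additionally carries a small ungated "trace
  oxidation" rate (methanogen co-metabolism) that converts CH4 to CO2
  without touching the sulfur pools; the sulfide-only condition carries
  background methanogenesis (CO2 -> CH4, drawing CO2 at its current
  isotopic composition), so methane accumulates there while unlabeled
  bottles stay at the natural-abundance baseline.
* The setpoint controller (FeCl2/Na2SO4/FeSO4) runs at every sampling
  visit (weekly), producing the characteristic sawtooth sulfide/sulfate
  traces and the amendment log.
* Growth: clade copies at day 344 = inoculum * (1 + background) +
  yield * niche * CH4 oxidized — a linear-yield simplification whose
  planted ranking (ANME-2a/b strongest under methane with high sulfate,
  suppressed under low sulfate with high sulfide) is what the analysis
  pipeline is expected to recover.

Measurement model: multiplicative lognormal noise (sigma = noise_sd) on
every observed concentration and gas amount, additive Gaussian noise on
qPCR Cq values, and a per-bottle lognormal rate multiplier for biological
replicate variability.  With all noise at zero, observations equal the
ground truth and the sulfur and carbon ledgers close to round-off.

One master seed drives everything; per-bottle streams are spawned from
it in fixed order, so identical seeds give bit-identical output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .control import (
    AmendmentAction,
    GeochemState,
    Setpoints,
    apply_amendments,
    required_amendments,
)
from .qpcr import CLADES
from .thermo import (
    IncubationCondition,
    TABLE1_CONDITIONS,
    ThermoParams,
    UndefinedQuotientError,
    delta_g_prime,
)
from .tracer import BottleSpec, headspace_amount

__all__ = [
    "SimParams",
    "ConditionSpec",
    "STUDY_CONDITIONS",
    "SyntheticStudy",
    "aom_rate",
    "step",
    "generate_study",
    "rate_curve",
    "fit_monod",
    "QPCR_SAMPLE_G_WET",
    "QPCR_EXTRACT_NG_PER_UL",
    "QPCR_ELUTION_UL",
    "QPCR_TEMPLATE_NG",
    "PLANTED_CURVES",
    "STANDARD_COPIES_PER_UL",
]

# qPCR back-calculation chain constants shared by generator and pipeline.
QPCR_SAMPLE_G_WET = 2.0
QPCR_EXTRACT_NG_PER_UL = 50.0
QPCR_ELUTION_UL = 50.0
QPCR_TEMPLATE_NG = 5.0

#: Planted calibration lines per clade target (slope -3.3219 = 100% efficiency).
PLANTED_CURVES = {
    "ANME1": (-3.3219, 37.2),
    "ANME2ab": (-3.3219, 36.8),
    "ANME2c": (-3.3219, 37.5),
}

#: 10-fold dilution series of the plasmid standards, copies per uL.
STANDARD_COPIES_PER_UL = tuple(2.0 * 10.0**e for e in range(5, -3, -1))


def _default_growth_yield() -> dict[str, float]:
    # copies per gram wet weight produced per mmol CH4 oxidized
    return {"ANME2ab": 1.0e8, "ANME1": 2.0e6, "ANME2c": 2.0e5}


def _default_clade_niche() -> dict[str, dict[str, float]]:
    # per-condition multiplier on the growth yield
    return {
        "ANME2ab": {
            "1_CH4_highSO4": 1.0,
            "2_CH4_highSO4_highS": 1.0,
            "3_CH4_lowSO4": 0.6,
            "4_CH4_lowSO4_highS": 0.0,
            "6_CH4_only": 1.0,
        },
        "ANME1": {
            "1_CH4_highSO4": 0.3,
            "2_CH4_highSO4_highS": 0.3,
            "3_CH4_lowSO4": 0.3,
            "6_CH4_only": 0.3,
        },
        "ANME2c": {},
    }


def _default_background_growth() -> dict[str, dict[str, float]]:
    # fractional day-344 copy gain independent of methane oxidation:
    # ANME-1 grows modestly everywhere, ANME-2c only with sulfate alone,
    # ANME-2a/b gets a small boost in the methane-only bottles.
    anme1 = {c.id: 0.3 for c in TABLE1_CONDITIONS}
    return {
        "ANME1": anme1,
        "ANME2c": {"5_highSO4": 1.5},
        "ANME2ab": {"6_CH4_only": 0.2},
    }


def _default_inoculum() -> dict[str, float]:
    # day-0 copies per gram wet weight: mostly ANME-2a/b, few ANME-1,
    # least ANME-2c
    return {"ANME2ab": 1.0e7, "ANME1": 1.0e6, "ANME2c": 1.0e5}


@dataclass(frozen=True)
class SimParams:
    """Rate-law, yield, noise and seeding parameters of the generator."""

    vmax_mM_per_day: float = 0.005
    km_sulfate_mM: float = 1.5  # half-saturation below the reported 2 mM
    dg_crit_kj: float = -19.0
    smooth_gate: bool = False
    gate_scale_kj: float = 1.0  # logistic width when smooth_gate is on
    methanogenesis_rate_mM_per_day: float = 0.002
    trace_oxidation_mM_per_day: float = 0.0005
    growth_yield: dict[str, float] = field(default_factory=_default_growth_yield)
    clade_niche: dict[str, dict[str, float]] = field(
        default_factory=_default_clade_niche
    )
    background_growth: dict[str, dict[str, float]] = field(
        default_factory=_default_background_growth
    )
    inoculum_copies: dict[str, float] = field(default_factory=_default_inoculum)
    noise_sd: float = 0.05
    cq_noise_sd: float = 0.1
    bottle_rate_sd: float = 0.10
    seed: int = 0
    dt_days: float = 1.0
    duration_days: int = 947
    label_start_day: float = 540.0
    f13_ch4_label: float = 0.12
    natural_abundance: float = 0.011
    sampling_interval_days: int = 7
    n_replicates: int = 3
    qpcr_days: tuple[int, int] = (0, 344)

    def __post_init__(self) -> None:
        if self.km_sulfate_mM <= 0:
            raise ValueError("km_sulfate_mM must be positive")
        for name in (
            "vmax_mM_per_day",
            "methanogenesis_rate_mM_per_day",
            "trace_oxidation_mM_per_day",
            "noise_sd",
            "cq_noise_sd",
            "bottle_rate_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt_days <= 0:
            raise ValueError("dt_days must be positive")
        ino = self.inoculum_copies
        if not ino["ANME2ab"] > ino["ANME1"] > ino["ANME2c"]:
            raise ValueError(
                "inoculum ordering must satisfy ANME2ab > ANME1 > ANME2c"
            )


@dataclass(frozen=True)
class ConditionSpec:
    """One study condition plus its control band and side processes."""

    condition: IncubationCondition
    setpoints: Setpoints
    methanogenic: bool = False
    trace_oxidation: bool = False


def _roster() -> tuple[ConditionSpec, ...]:
    by_id = {c.id: c for c in TABLE1_CONDITIONS}
    return (
        ConditionSpec(
            by_id["1_CH4_highSO4"], Setpoints(0.4, 1.0, 21.6, 18.0)
        ),
        ConditionSpec(
            by_id["2_CH4_highSO4_highS"], Setpoints(3.8, 4.5, 21.1, 18.0)
        ),
        ConditionSpec(
            by_id["3_CH4_lowSO4"], Setpoints(0.4, 1.0, 3.6, 2.5)
        ),
        ConditionSpec(
            by_id["4_CH4_lowSO4_highS"], Setpoints(3.6, 4.5, 4.0, 2.5)
        ),
        ConditionSpec(
            by_id["5_highSO4"], Setpoints(0.2, 1.0, 21.6, 18.0)
        ),
        # endogenous sulfate only: never replenished (floor 0)
        ConditionSpec(
            by_id["6_CH4_only"],
            Setpoints(0.1, 1.0, 0.1, 0.0),
            trace_oxidation=True,
        ),
        ConditionSpec(
            by_id["7_highS"],
            Setpoints(3.0, 4.5, 0.4, 0.0),
            methanogenic=True,
        ),
    )


STUDY_CONDITIONS: tuple[ConditionSpec, ...] = _roster()


@dataclass
class _BottleState:
    """Internal mutable per-bottle state (noiseless ground truth)."""

    bottle_id: str
    condition_id: str
    day: float
    sulfate_mM: float
    sulfide_mM: float
    fes_mmol: float
    ch4_headspace_mmol: float
    ch4_aq_12_mmol: float
    ch4_aq_13_mmol: float
    co2_12_mmol: float
    co2_13_mmol: float
    f13_ch4: float
    cum_ox_mmol: float = 0.0
    cum_ox_post_label_mmol: float = 0.0
    liquid_volume_L: float = 0.120

    @property
    def co2_mmol(self) -> float:
        return self.co2_12_mmol + self.co2_13_mmol

    @property
    def co2_mM(self) -> float:
        return self.co2_mmol / self.liquid_volume_L

    @property
    def ch4_aq_mM(self) -> float:
        return (self.ch4_aq_12_mmol + self.ch4_aq_13_mmol) / self.liquid_volume_L

    @property
    def ch4_carbon_mmol(self) -> float:
        return (
            self.ch4_headspace_mmol + self.ch4_aq_12_mmol + self.ch4_aq_13_mmol
        )


def aom_rate(
    sulfate_mM: float,
    sulfide_mM: float,
    co2_mM: float,
    methane_mM: float,
    p: SimParams,
    thermo: ThermoParams = ThermoParams(),
) -> float:
    """Sulfate-coupled AOM rate (mM CH4 per day in the liquid phase).

    Monod kinetics in sulfate multiplied by an energetic gate: with the
    hard gate (default) the rate is zero unless dG' <= dg_crit; the
    smooth variant uses a logistic factor of width ``gate_scale_kj``.
    Zero whenever methane or sulfate is absent.
    """
    if methane_mM <= 0 or sulfate_mM <= 0:
        return 0.0
    cond = IncubationCondition(
        "state", sulfate_mM, sulfide_mM, methane_mM, max(co2_mM, 0.0)
    )
    try:
        dg = delta_g_prime(cond, thermo)
    except UndefinedQuotientError:
        return 0.0
    if p.smooth_gate:
        gate = 1.0 / (1.0 + np.exp((dg - p.dg_crit_kj) / p.gate_scale_kj))
    else:
        gate = 1.0 if dg <= p.dg_crit_kj else 0.0
    monod = sulfate_mM / (p.km_sulfate_mM + sulfate_mM)
    return p.vmax_mM_per_day * monod * gate


def step(
    state: _BottleState,
    cspec: ConditionSpec,
    p: SimParams,
    dt: float,
    rate_multiplier: float = 1.0,
) -> _BottleState:
    """Advance one bottle by ``dt`` days (forward Euler, in place).

    Applies AOM (1:1:1 stoichiometry, isotopologue-resolved CO2
    production), trace oxidation and methanogenesis where enabled, and
    the day-540 label switch.  Pools that would go negative are clipped
    at zero with a warning (does not occur at default parameters).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cond = cspec.condition
    v = state.liquid_volume_L
    methane_mM = 1.31 if cond.methane_added else state.ch4_aq_mM

    if cond.methane_added and state.day >= p.label_start_day:
        state.f13_ch4 = p.f13_ch4_label

    r = rate_multiplier * aom_rate(
        state.sulfate_mM, state.sulfide_mM, state.co2_mM, methane_mM, p
    )
    d_mM = min(r * dt, state.sulfate_mM)  # cannot reduce more than is there
    if r * dt > state.sulfate_mM:
        warnings.warn(f"{state.bottle_id}: sulfate pool clipped at 0")
    state.sulfate_mM -= d_mM
    state.sulfide_mM += d_mM
    ox_mmol = d_mM * v

    if cspec.trace_oxidation:
        trace_mmol = rate_multiplier * p.trace_oxidation_mM_per_day * dt * v
        ox_mmol += trace_mmol

    if ox_mmol > 0:
        ox_mmol = min(ox_mmol, state.ch4_headspace_mmol)
        state.ch4_headspace_mmol -= ox_mmol
        state.co2_13_mmol += ox_mmol * state.f13_ch4
        state.co2_12_mmol += ox_mmol * (1.0 - state.f13_ch4)
        state.cum_ox_mmol += ox_mmol
        if state.day >= p.label_start_day:
            state.cum_ox_post_label_mmol += ox_mmol

    if cspec.methanogenic:
        # CO2 is drawn at its current isotopic composition, so no-label
        # bottles stay at the natural-abundance baseline
        m_mmol = rate_multiplier * p.methanogenesis_rate_mM_per_day * dt * v
        if m_mmol > state.co2_mmol:
            warnings.warn(f"{state.bottle_id}: CO2 pool clipped at 0")
            m_mmol = state.co2_mmol
        f_co2 = state.co2_13_mmol / state.co2_mmol if state.co2_mmol > 0 else 0.0
        state.co2_13_mmol -= m_mmol * f_co2
        state.co2_12_mmol -= m_mmol * (1.0 - f_co2)
        state.ch4_aq_13_mmol += m_mmol * f_co2
        state.ch4_aq_12_mmol += m_mmol * (1.0 - f_co2)

    state.day += dt
    return state


@dataclass
class SyntheticStudy:
    """Everything one study run produces, observations plus ground truth."""

    params: SimParams
    conditions: tuple[ConditionSpec, ...]
    geochem: pd.DataFrame
    gas: pd.DataFrame
    amendments: pd.DataFrame
    qpcr_plates: pd.DataFrame
    truth: dict
    histories: dict[str, list[tuple[GeochemState, list[AmendmentAction]]]]

    def write_csvs(self, outdir: str | Path) -> dict[str, Path]:
        """Write the CSV dialects consumed downstream plus the truth ledger."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("geochem", self.geochem),
            ("gas", self.gas),
            ("amendments", self.amendments),
            ("qpcr_plates", self.qpcr_plates),
        ):
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        paths["ground_truth"] = truth_path
        return paths


def _lognoise(rng: np.random.Generator, sd: float) -> float:
    return float(np.exp(rng.normal(0.0, sd))) if sd > 0 else 1.0


def _simulate_bottle(
    cspec: ConditionSpec,
    bottle_id: str,
    p: SimParams,
    rng: np.random.Generator,
) -> dict:
    cond = cspec.condition
    spec = BottleSpec()
    v = spec.liquid_volume_L
    rate_multiplier = _lognoise(rng, p.bottle_rate_sd)

    co2_total = cond.co2_mM * v
    state = _BottleState(
        bottle_id=bottle_id,
        condition_id=cond.id,
        day=0.0,
        sulfate_mM=cond.sulfate_mM,
        sulfide_mM=cond.sulfide_mM,
        fes_mmol=0.0,
        ch4_headspace_mmol=(
            headspace_amount(spec, spec.headspace_pressure_bar)
            if cond.methane_added
            else 0.0
        ),
        ch4_aq_12_mmol=0.0,
        ch4_aq_13_mmol=0.0,
        co2_12_mmol=co2_total * (1.0 - p.natural_abundance),
        co2_13_mmol=co2_total * p.natural_abundance,
        f13_ch4=p.natural_abundance if cond.methane_added else 0.0,
        liquid_volume_L=v,
    )

    def geochem_view() -> GeochemState:
        return GeochemState(
            day=state.day,
            sulfate_mM=state.sulfate_mM,
            sulfide_mM=state.sulfide_mM,
            fes_mmol=state.fes_mmol,
            liquid_volume_L=v,
        )

    history: list[tuple[GeochemState, list[AmendmentAction]]] = [
        (geochem_view(), [])
    ]
    geochem_rows: list[dict] = []
    gas_rows: list[dict] = []
    amendment_rows: list[dict] = []
    cum_ox_at: dict[int, float] = {}

    carbon0 = state.ch4_carbon_mmol + state.co2_mmol
    co2_13_at_label = None

    def observe() -> None:
        dissolved_ch4 = 1.31 if cond.methane_added else state.ch4_aq_mM
        geochem_rows.append(
            {
                "bottle_id": bottle_id,
                "condition_id": cond.id,
                "day": state.day,
                "sulfate_mM": state.sulfate_mM * _lognoise(rng, p.noise_sd),
                "sulfide_mM": state.sulfide_mM * _lognoise(rng, p.noise_sd),
                "ch4_mM": dissolved_ch4 * _lognoise(rng, p.noise_sd),
                "co2_mM": state.co2_mM * _lognoise(rng, p.noise_sd),
            }
        )
        ch4_total = state.ch4_carbon_mmol
        ch4_13 = (
            state.ch4_headspace_mmol * state.f13_ch4 + state.ch4_aq_13_mmol
        )
        for species, a12, a13 in (
            ("CO2", state.co2_12_mmol, state.co2_13_mmol),
            ("CH4", ch4_total - ch4_13, ch4_13),
        ):
            gas_rows.append(
                {
                    "bottle_id": bottle_id,
                    "day": state.day,
                    "species": species,
                    "amount12_mmol": a12 * _lognoise(rng, p.noise_sd),
                    "amount13_mmol": a13 * _lognoise(rng, p.noise_sd),
                }
            )

    observe()  # day 0
    cum_ox_at[0] = 0.0

    day = 0
    while day < p.duration_days:
        step(state, cspec, p, p.dt_days, rate_multiplier)
        day = int(round(state.day))
        is_visit = (
            day % p.sampling_interval_days == 0 or day == p.duration_days
        )
        if is_visit:
            actions = required_amendments(geochem_view(), cspec.setpoints)
            if actions:
                new = apply_amendments(geochem_view(), actions)
                state.sulfate_mM = new.sulfate_mM
                state.sulfide_mM = new.sulfide_mM
                state.fes_mmol = new.fes_mmol
                for a in actions:
                    amendment_rows.append(
                        {
                            "bottle_id": bottle_id,
                            "day": day,
                            "reagent": a.reagent,
                            "dose_mmol": a.dose_mmol,
                        }
                    )
            history.append((geochem_view(), actions))
            observe()
        if co2_13_at_label is None and state.day >= p.label_start_day:
            co2_13_at_label = state.co2_13_mmol
        if day in p.qpcr_days:
            cum_ox_at[day] = state.cum_ox_mmol

    for d in p.qpcr_days:
        cum_ox_at.setdefault(d, state.cum_ox_mmol)

    copies: dict[str, dict[int, float]] = {}
    for clade in CLADES:
        day0 = p.inoculum_copies[clade]
        bg = p.background_growth.get(clade, {}).get(cond.id, 0.0)
        niche = p.clade_niche.get(clade, {}).get(cond.id, 0.0)
        gained = p.growth_yield[clade] * niche * cum_ox_at[p.qpcr_days[1]]
        copies[clade] = {
            p.qpcr_days[0]: day0,
            p.qpcr_days[1]: day0 * (1.0 + bg) + gained,
        }

    truth = {
        "condition_id": cond.id,
        "rate_multiplier": rate_multiplier,
        "cum_ch4_oxidized_mmol": state.cum_ox_mmol,
        "cum_ch4_oxidized_post_label_mmol": state.cum_ox_post_label_mmol,
        "cum_ch4_oxidized_at_qpcr_mmol": cum_ox_at,
        "delta_13co2_post_label_mmol": (
            state.co2_13_mmol - co2_13_at_label
            if co2_13_at_label is not None
            else 0.0
        ),
        "copies_per_g_wet": copies,
        "final_state": {
            "day": state.day,
            "sulfate_mM": state.sulfate_mM,
            "sulfide_mM": state.sulfide_mM,
            "fes_mmol": state.fes_mmol,
            "ch4_aq_mM": state.ch4_aq_mM,
            "co2_mM": state.co2_mM,
            "f13_ch4": state.f13_ch4,
        },
        "carbon_residual_mmol": (
            state.ch4_carbon_mmol + state.co2_mmol - carbon0
        ),
    }
    return {
        "geochem": geochem_rows,
        "gas": gas_rows,
        "amendments": amendment_rows,
        "history": history,
        "truth": truth,
        "copies": copies,
    }


def _qpcr_plates(
    bottle_copies: dict[str, dict[str, dict[int, float]]],
    p: SimParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emit standards and sample wells through the planted calibrations."""
    rows: list[dict] = []
    for clade in CLADES:
        slope, intercept = PLANTED_CURVES[clade]
        plate_id = f"plate_{clade}"
        for copies_ul in STANDARD_COPIES_PER_UL:
            for _ in range(3):
                cq = intercept + slope * np.log10(copies_ul)
                if p.cq_noise_sd > 0:
                    cq += rng.normal(0.0, p.cq_noise_sd)
                rows.append(
                    {
                        "plate_id": plate_id,
                        "target": clade,
                        "well_type": "standard",
                        "bottle_id": "",
                        "day": "",
                        "copies_per_ul": copies_ul,
                        "cq": cq,
                        "template_ng": "",
                        "sample_g_wet": "",
                        "extract_ng_per_ul": "",
                        "elution_ul": "",
                    }
                )
        total_ng = QPCR_EXTRACT_NG_PER_UL * QPCR_ELUTION_UL
        for bottle_id, per_clade in bottle_copies.items():
            for day, copies_g in per_clade[clade].items():
                copies_rxn = (
                    copies_g
                    * QPCR_SAMPLE_G_WET
                    / total_ng
                    * QPCR_TEMPLATE_NG
                )
                cq = intercept + slope * np.log10(copies_rxn)
                if p.cq_noise_sd > 0:
                    cq += rng.normal(0.0, p.cq_noise_sd)
                rows.append(
                    {
                        "plate_id": plate_id,
                        "target": clade,
                        "well_type": "sample",
                        "bottle_id": bottle_id,
                        "day": day,
                        "copies_per_ul": "",
                        "cq": cq,
                        "template_ng": QPCR_TEMPLATE_NG,
                        "sample_g_wet": QPCR_SAMPLE_G_WET,
                        "extract_ng_per_ul": QPCR_EXTRACT_NG_PER_UL,
                        "elution_ul": QPCR_ELUTION_UL,
                    }
                )
    return pd.DataFrame(rows)


def generate_study(p: SimParams = SimParams()) -> SyntheticStudy:
    """Run the full synthetic study: 7 conditions x triplicate x 947 days."""
    master = np.random.SeedSequence(p.seed)
    n_bottles = len(STUDY_CONDITIONS) * p.n_replicates
    children = master.spawn(n_bottles + 1)

    geochem_rows: list[dict] = []
    gas_rows: list[dict] = []
    amendment_rows: list[dict] = []
    histories: dict[str, list] = {}
    truth_bottles: dict[str, dict] = {}
    bottle_copies: dict[str, dict[str, dict[int, float]]] = {}

    idx = 0
    for cspec in STUDY_CONDITIONS:
        for rep in "ABC"[: p.n_replicates]:
            bottle_id = f"{cspec.condition.id}_{rep}"
            rng = np.random.default_rng(children[idx])
            idx += 1
            out = _simulate_bottle(cspec, bottle_id, p, rng)
            geochem_rows.extend(out["geochem"])
            gas_rows.extend(out["gas"])
            amendment_rows.extend(out["amendments"])
            histories[bottle_id] = out["history"]
            truth_bottles[bottle_id] = out["truth"]
            bottle_copies[bottle_id] = out["copies"]

    qpcr_rng = np.random.default_rng(children[-1])
    plates = _qpcr_plates(bottle_copies, p, qpcr_rng)

    truth = {
        "params": {
            "vmax_mM_per_day": p.vmax_mM_per_day,
            "km_sulfate_mM": p.km_sulfate_mM,
            "dg_crit_kj": p.dg_crit_kj,
            "f13_ch4_label": p.f13_ch4_label,
            "seed": p.seed,
        },
        "bottles": truth_bottles,
    }
    return SyntheticStudy(
        params=p,
        conditions=STUDY_CONDITIONS,
        geochem=pd.DataFrame(geochem_rows),
        gas=pd.DataFrame(gas_rows),
        amendments=pd.DataFrame(
            amendment_rows,
            columns=["bottle_id", "day", "reagent", "dose_mmol"],
        ),
        qpcr_plates=plates,
        truth=truth,
        histories=histories,
    )


def rate_curve(
    p: SimParams,
    sulfate_grid_mM: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """AOM rate at each sulfate level with the gate held open.

    Evaluates the Monod law at low product concentrations (sulfide and
    CO2 well below equilibrium, dG' deeply negative), optionally with
    multiplicative lognormal noise — the synthetic analogue of a
    rate-versus-sulfate batch assay used for parameter recovery.
    """
    grid = np.asarray(sulfate_grid_mM, dtype=float)
    rates = np.array(
        [aom_rate(s, 0.1, 1.0, 1.31, p) for s in grid]
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(p.seed)
        rates = rates * np.exp(rng.normal(0.0, noise_sd, size=rates.shape))
    return rates


def fit_monod(
    sulfate_mM: Sequence[float], rates: Sequence[float]
) -> tuple[float, float]:
    """Least-squares Monod fit; returns (vmax, Km)."""

    def monod(s, vmax, km):
        return vmax * s / (km + s)

    popt, _ = curve_fit(
        monod,
        np.asarray(sulfate_mM, dtype=float),
        np.asarray(rates, dtype=float),
        p0=(0.01, 1.0),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])
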