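"""Setpoint maintenance of sulfate and sulfide in batch incubations.

During the incubations sulfide accumulates (AOM product) and sulfate is
consumed, so both were periodically corrected with reagent additions:

* FeCl2 precipitates excess dissolved sulfide as FeS (1:1 Fe:S),
* Na2SO4 replenishes sulfate,
* FeSO4 does both at once (one mol precipitates one mol sulfide and
  delivers one mol sulfate).

The controller below reproduces that logic: whenever sulfide exceeds its
ceiling or sulfate falls below its floor, doses are computed that restore
the *target* concentrations exactly (producing the sawtooth time courses
seen in monitored bottles).  When both corrections are needed at once,
FeSO4 covers min(excess sulfide, sulfate deficit) and single-purpose
reagents top up the remainder, so neither setpoint is overshot.

FeS precipitation is treated as instantaneous, complete and irreversible;
dissolved pools are concentrations (mM) over the bottle's liquid volume,
reagent doses are absolute amounts (mmol).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

__all__ = [
    "GeochemState",
    "Setpoints",
    "AmendmentAction",
    "REAGENTS",
    "required_amendments",
    "apply_amendment",
    "apply_amendments",
    "sulfur_balance",
]

REAGENTS = ("FeCl2", "Na2SO4", "FeSO4")


@dataclass(frozen=True)
class GeochemState:
    """Dissolved sulfur pools of one bottle at one time."""

    day: float
    sulfate_mM: float
    sulfide_mM: float
    fes_mmol: float = 0.0  # cumulative precipitated sulfide
    liquid_volume_L: float = 0.120

    def __post_init__(self) -> None:
        if min(self.sulfate_mM, self.sulfide_mM, self.fes_mmol) < 0:
            raise ValueError("sulfur pools must be >= 0")
        if self.liquid_volume_L <= 0:
            raise ValueError("liquid volume must be positive")

    @property
    def total_sulfur_mmol(self) -> float:
        """Dissolved sulfate + dissolved sulfide + FeS pool, in mmol.

        The FeS pool is the cumulative sulfide removed from solution, so
        it appears exactly once in the inventory.
        """
        return (
            (self.sulfate_mM + self.sulfide_mM) * self.liquid_volume_L
            + self.fes_mmol
        )


@dataclass(frozen=True)
class Setpoints:
    """Per-condition control band: sulfide ceiling, sulfate floor, targets."""

    sulfide_target_mM: float
    sulfide_max_mM: float
    sulfate_target_mM: float
    sulfate_min_mM: float

    def __post_init__(self) -> None:
        if not self.sulfide_max_mM >= self.sulfide_target_mM >= 0:
            raise ValueError("need sulfide_max >= sulfide_target >= 0")
        if not self.sulfate_target_mM >= self.sulfate_min_mM >= 0:
            raise ValueError("need sulfate_target >= sulfate_min >= 0")


@dataclass(frozen=True)
class AmendmentAction:
    reagent: str
    dose_mmol: float

    def __post_init__(self) -> None:
        if self.reagent not in REAGENTS:
            raise ValueError(f"unknown reagent {self.reagent!r}")
        if self.dose_mmol < 0:
            raise ValueError("dose must be >= 0")


def required_amendments(
    state: GeochemState, sp: Setpoints
) -> list[AmendmentAction]:
    """Doses restoring the target concentrations, empty when in band.

    Excess sulfide n1 = (sulfide - target)*V if sulfide > ceiling, else 0;
    sulfate deficit n2 = (target - sulfate)*V if sulfate < floor, else 0.
    If both are positive, FeSO4 covers min(n1, n2) and FeCl2 / Na2SO4 top
    up the remainder; otherwise a single-purpose reagent handles whichever
    is positive.
    """
    v = state.liquid_volume_L
    n1 = (
        (state.sulfide_mM - sp.sulfide_target_mM) * v
        if state.sulfide_mM > sp.sulfide_max_mM
        else 0.0
    )
    n2 = (
        (sp.sulfate_target_mM - state.sulfate_mM) * v
        if state.sulfate_mM < sp.sulfate_min_mM
        else 0.0
    )
    actions: list[AmendmentAction] = []
    if n1 > 0 and n2 > 0:
        shared = min(n1, n2)
        actions.append(AmendmentAction("FeSO4", shared))
        if n1 > shared:
            actions.append(AmendmentAction("FeCl2", n1 - shared))
        if n2 > shared:
            actions.append(AmendmentAction("Na2SO4", n2 - shared))
    elif n1 > 0:
        actions.append(AmendmentAction("FeCl2", n1))
    elif n2 > 0:
        actions.append(AmendmentAction("Na2SO4", n2))
    return actions


def apply_amendment(state: GeochemState, a: AmendmentAction) -> GeochemState:
    """New state after one reagent addition (1:1 FeS stoichiometry)."""
    v = state.liquid_volume_L
    sulfide = state.sulfide_mM
    sulfate = state.sulfate_mM
    fes = state.fes_mmol
    if a.reagent in ("FeCl2", "FeSO4"):
        precipitated = min(a.dose_mmol, sulfide * v)
        sulfide -= precipitated / v
        fes += precipitated
    if a.reagent in ("Na2SO4", "FeSO4"):
        sulfate += a.dose_mmol / v
    return replace(state, sulfate_mM=sulfate, sulfide_mM=sulfide, fes_mmol=fes)


def apply_amendments(
    state: GeochemState, actions: Iterable[AmendmentAction]
) -> GeochemState:
    for a in actions:
        state = apply_amendment(state, a)
    return state


def sulfur_balance(
    history: Sequence[tuple[GeochemState, Sequence[AmendmentAction]]],
) -> float:
    """Residual of the sulfur mass balance over a bottle history, mmol.

    ``history`` pairs each recorded state with the amendments applied
    since the previous record (a bare :class:`AmendmentAction` is also
    accepted); states are therefore post-amendment, and the initial entry
    carries no amendments.  The residual is

        inventory(last) - inventory(first) - sulfur added by amendments

    where the inventory counts dissolved sulfate, dissolved sulfide and
    the FeS pool, and Na2SO4 / FeSO4 each add one mol S per mol dose
    (FeCl2 adds none; AOM converts sulfate to sulfide 1:1 and conserves
    sulfur).  Zero in a closed noiseless system.
    """
    if not history:
        return 0.0
    days = [state.day for state, _ in history]
    if days != sorted(days):
        raise ValueError("history must be in chronological order")
    added = 0.0
    for _, actions in history:
        if isinstance(actions, AmendmentAction):
            actions = [actions]
        for a in actions:
            if a.reagent in ("Na2SO4", "FeSO4"):
                added += a.dose_mmol
    first = history[0][0]
    last = history[-1][0]
    return last.total_sulfur_mmol - first.total_sulfur_mmol - added
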