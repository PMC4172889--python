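"""Discrete-time simulation of a fractionated radiotherapy course.

The simulator advances a tumorlet's compartment state in small time steps
(default 1 h). Each step applies, in order:

1. **Proliferation in P.** A density-dependent fraction of P-cells is in
   cycle; the cohort dividing during ``dt`` is
   ``proliferating_fraction(occupancy) * dt / cell_cycle_time`` of the
   compartment. A dividing viable cell adds one viable daughter. A
   dividing doomed cell attempts mitosis and dies: in expectation it is
   replaced by ``2 * progeny_survival`` doomed cells (0.6 at defaults),
   which is how lethally damaged cells actually disappear from the system.
2. **Starvation loss in H.** Exponential decay with the configured
   half-time, applied to viable and doomed cells alike.
3. **Recompartmentalization.** The P-compartment always takes as many
   cells from I as its capacity allows (reoxygenation), I refills from H,
   and overflow moves the opposite way (P -> I -> H). Transfers draw
   viable and doomed cells in proportion to their abundance in the source.

At the scheduled fraction times (5 fractions/week: treatment on days 0-4
of each 7-day week, delivered instantaneously at the start of the day,
before that day's kinetics) a fraction of the *viable* cells of each
compartment becomes doomed per the compartment's LQ survival with OER.

Everything is expected-value bookkeeping: the model is fully
deterministic and cell counts are continuous. All state fields may be
scalars (one tumorlet) or equal-length arrays (a whole scenario grid
advanced in lockstep), which is what makes the 1315-scenario sweep cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import (
    ArrayLike,
    CompartmentState,
    lq_surviving_fraction,
    proliferating_fraction,
)
from .grid import Scenario
from .params import TumorletParams

__all__ = [
    "Schedule",
    "SimulationResult",
    "step",
    "apply_fraction",
    "recompartmentalize",
    "simulate_course",
    "run_course",
]


@dataclass(frozen=True)
class Schedule:
    """Fraction times (in days) for an n-fraction, 5-per-week course."""

    fraction_dose: float
    fraction_times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.fraction_times)
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("fraction times must be non-negative, strictly increasing")

    @classmethod
    def weekly(
        cls, n_fractions: int, fraction_dose: float = 2.0, per_week: int = 5
    ) -> "Schedule":
        """Mon-Fri pattern: days 0-4, 7-11, 14-18, ... at ``per_week`` = 5."""
        times = tuple(
            float(7 * (k // per_week) + k % per_week) for k in range(n_fractions)
        )
        return cls(fraction_dose=fraction_dose, fraction_times=times)


@dataclass
class SimulationResult:
    """Course outcome: per-fraction snapshots and the final clonogen count.

    ``surviving_clonogens`` is ``clonogenic_fraction`` times the total
    viable count immediately after the last fraction (no post-treatment
    regrowth window).
    """

    snapshots: list[CompartmentState]
    end_viable_total: float
    surviving_clonogens: float


def _proportional_split(
    amount: ArrayLike, viable: ArrayLike, doomed: ArrayLike
) -> tuple[ArrayLike, ArrayLike]:
    """Split a transfer ``amount`` into viable/doomed parts proportional to
    the source composition. ``amount`` must not exceed viable + doomed."""
    total = viable + doomed
    safe = np.where(np.asarray(total) > 0, total, 1.0)
    moved_v = amount * (viable / safe)
    return moved_v, amount - moved_v


def recompartmentalize(state: CompartmentState) -> CompartmentState:
    """Rebalance compartments against their fixed capacities.

    Stage 1 (P <-> I): a deficit in P is filled from I (reoxygenation);
    overflow in P spills into I. Stage 2 (I <-> H): likewise between I and
    the unbounded H. A P-deficit with an empty I is therefore only
    replenished from H via I on subsequent calls — the chain respects the
    P-from-I-first ordering. Total cell count is conserved exactly.
    """
    s = state.copy()

    # --- stage 1: P <-> I ---
    occ_p = s.viable_p + s.doomed_p
    overflow = np.maximum(occ_p - s.cap_p, 0.0)
    deficit = np.minimum(np.maximum(s.cap_p - occ_p, 0.0), s.viable_i + s.doomed_i)
    mv, md = _proportional_split(overflow, s.viable_p, s.doomed_p)
    s.viable_p = s.viable_p - mv
    s.doomed_p = s.doomed_p - md
    s.viable_i = s.viable_i + mv
    s.doomed_i = s.doomed_i + md
    mv, md = _proportional_split(deficit, s.viable_i, s.doomed_i)
    s.viable_i = s.viable_i - mv
    s.doomed_i = s.doomed_i - md
    s.viable_p = s.viable_p + mv
    s.doomed_p = s.doomed_p + md

    # --- stage 2: I <-> H ---
    occ_i = s.viable_i + s.doomed_i
    overflow = np.maximum(occ_i - s.cap_i, 0.0)
    deficit = np.minimum(np.maximum(s.cap_i - occ_i, 0.0), s.viable_h + s.doomed_h)
    mv, md = _proportional_split(overflow, s.viable_i, s.doomed_i)
    s.viable_i = s.viable_i - mv
    s.doomed_i = s.doomed_i - md
    s.viable_h = s.viable_h + mv
    s.doomed_h = s.doomed_h + md
    mv, md = _proportional_split(deficit, s.viable_h, s.doomed_h)
    s.viable_h = s.viable_h - mv
    s.doomed_h = s.doomed_h - md
    s.viable_i = s.viable_i + mv
    s.doomed_i = s.doomed_i + md
    return s


def step(
    state: CompartmentState, params: TumorletParams, dt: float | None = None
) -> CompartmentState:
    """Advance the state by one time step of ``dt`` hours.

    Order: proliferation in P, starvation loss in H, then
    recompartmentalization. Total cell count changes only through births
    (viable divisions) and deaths (mitotic death of doomed dividers,
    starvation in H).
    """
    dt = params.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = state.copy()

    # 1. proliferation in P (occupancy measured before this step's births)
    occ = np.where(
        np.asarray(s.cap_p) > 0,
        (s.viable_p + s.doomed_p) / np.where(np.asarray(s.cap_p) > 0, s.cap_p, 1.0),
        0.0,
    )
    pf = proliferating_fraction(occ, params.prolif_frac_low, params.prolif_frac_full)
    # dividing cohort sized so a fully proliferating population doubles in
    # exactly one cell_cycle_time irrespective of dt
    div_rate = pf * (2.0 ** (dt / (params.cell_cycle_time * 24.0)) - 1.0)
    s.viable_p = s.viable_p + div_rate * s.viable_p
    # doomed dividers die at mitosis, leaving 2*progeny_survival doomed progeny
    s.doomed_p = s.doomed_p - (1.0 - 2.0 * params.progeny_survival) * div_rate * s.doomed_p

    # 2. starvation loss in H
    decay = 2.0 ** (-dt / (params.h_loss_half_time * 24.0))
    s.viable_h = s.viable_h * decay
    s.doomed_h = s.doomed_h * decay

    # 3. rebalance against capacities
    s = recompartmentalize(s)
    if np.any(np.asarray(s.total) < 0):
        raise ValueError("negative total cell count after step")
    return s


def apply_fraction(
    state: CompartmentState, params: TumorletParams, dose: float | None = None
) -> CompartmentState:
    """Deliver one radiation fraction: per compartment, the viable cells
    survive with their LQ/OER fraction and the rest become doomed.
    Per-compartment totals are unchanged (doomed cells stay in place)."""
    dose = params.fraction_dose if dose is None else dose
    s = state.copy()
    for viable_attr, doomed_attr, oer in (
        ("viable_p", "doomed_p", params.oer_p),
        ("viable_i", "doomed_i", params.oer_i),
        ("viable_h", "doomed_h", params.oer_h),
    ):
        sf = lq_surviving_fraction(dose, oer, params)
        viable = getattr(s, viable_attr)
        newly_doomed = viable * (1.0 - sf)
        setattr(s, viable_attr, viable - newly_doomed)
        setattr(s, doomed_attr, getattr(s, doomed_attr) + newly_doomed)
    return s


def run_course(
    state: CompartmentState,
    params: TumorletParams,
    max_fractions: int,
    after_fraction: Callable[[int, CompartmentState], bool] | None = None,
) -> CompartmentState:
    """Drive a state through a 5-fractions/week course.

    Fractions are delivered at the start of their day, before that day's
    kinetic steps; weekend days get kinetics only. ``after_fraction(k,
    state)`` is called immediately after fraction ``k`` (1-based) and may
    return ``True`` to stop the course early. Returns the state at the
    moment the course ends (immediately after the last fraction).
    """
    if max_fractions < 0:
        raise ValueError("max_fractions must be non-negative")
    steps_per_day = int(round(24.0 / params.dt))
    per_week = params.fractions_per_week
    k = 0  # fractions delivered
    day = 0
    while k < max_fractions:
        is_treatment_day = (day % 7) < per_week
        if is_treatment_day:
            try:
                state = apply_fraction(state, params)
            except ValueError as exc:
                raise ValueError(f"fraction {k + 1}: {exc}") from exc
            k += 1
            if after_fraction is not None and after_fraction(k, state):
                return state
            if k >= max_fractions:
                return state
        for _ in range(steps_per_day):
            try:
                state = step(state, params)
            except ValueError as exc:
                raise ValueError(f"day {day}, after fraction {k}: {exc}") from exc
        day += 1
    return state


def simulate_course(
    scenario: Scenario, params: TumorletParams, n_fractions: int
) -> SimulationResult:
    """Simulate a full course for one scenario.

    Returns per-fraction snapshots (state immediately after each
    fraction) and the surviving clonogen count at the end of the course,
    ``clonogenic_fraction * total_viable`` right after the last fraction.
    With ``n_fractions = 0`` no time passes and the survivors are the
    initial clonogens.
    """
    snapshots: list[CompartmentState] = []

    def record(_k: int, s: CompartmentState) -> bool:
        snapshots.append(s.copy())
        return False

    state = scenario.initial_state.copy()
    end_state = run_course(state, params, n_fractions, after_fraction=record)
    end_viable = float(np.asarray(end_state.total_viable))
    return SimulationResult(
        snapshots=snapshots,
        end_viable_total=end_viable,
        surviving_clonogens=params.clonogenic_fraction * end_viable,
    )
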