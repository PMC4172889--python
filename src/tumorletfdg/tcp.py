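"""Tumor control probability and TD50 estimation.

Cure requires killing every clonogen. With expected surviving clonogen
number ``S``, the Poisson formalism gives ``TCP = exp(-S)``, so the 50%
control point is crossed when ``S`` falls through ``ln 2``.

TD50 is reported as total physical dose at the configured dose per
fraction. A single simulated course yields the survivor curve ``S(n)``
for every fraction count ``n`` at once, because the state immediately
after fraction ``n`` does not depend on later fractions; the first
integer bracket ``S(n_low) > ln 2 >= S(n_low + 1)`` is then refined by
log-linear interpolation of clonogen survival in dose:

    TD50 = d * (n_low + (ln S(n_low) - ln ln 2) / (ln S(n_low) - ln S(n_high)))

For a pure-exponential survival curve (no repopulation) this
interpolation is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import init_compartments
from .grid import Scenario
from .params import TumorletParams
from .simulate import run_course

__all__ = ["TD50Result", "poisson_tcp", "find_td50", "td50_sweep"]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class TD50Result:
    """TD50 for one scenario with its bracketing fraction counts."""

    gf: float
    clf: float
    td50: float
    n_low: int
    n_high: int
    tcp_low: float
    tcp_high: float

    def __post_init__(self) -> None:
        if not (self.tcp_low < 0.5 <= self.tcp_high):
            raise ValueError("bracket does not straddle TCP = 0.5")


def poisson_tcp(surviving_clonogens: float | np.ndarray) -> float | np.ndarray:
    """Probability of tumor control given the expected clonogen survivors."""
    s = np.asarray(surviving_clonogens, dtype=float)
    if np.any(s < 0):
        raise ValueError("surviving clonogen count must be non-negative")
    out = np.exp(-s)
    return float(out) if out.ndim == 0 else out


def interpolate_td50(
    n_low: np.ndarray | int,
    s_low: np.ndarray | float,
    s_high: np.ndarray | float,
    fraction_dose: float,
) -> np.ndarray | float:
    """Log-linear-in-dose interpolation of the TCP = 0.5 crossing."""
    n_low = np.asarray(n_low, dtype=float)
    frac = (np.log(s_low) - math.log(_LN2)) / (np.log(s_low) - np.log(s_high))
    out = fraction_dose * (n_low + frac)
    return float(out) if out.ndim == 0 else out


def _survival_brackets(
    gf: np.ndarray,
    clf: np.ndarray,
    params: TumorletParams,
    max_fractions: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run one long vectorized course and locate, per scenario, the first
    fraction count at which clonogen survival falls to ln 2 or below.

    Returns (n_low, s_low, s_high); raises if any scenario fails to reach
    TCP = 0.5 within ``max_fractions``.
    """
    state = init_compartments(np.asarray(gf, float), np.asarray(clf, float), params)
    cf = params.clonogenic_fraction
    n = np.asarray(gf).size

    s_prev = np.full(n, cf * params.n_cells)  # S(0)
    n_low = np.full(n, -1, dtype=int)
    s_low = np.zeros(n)
    s_high = np.zeros(n)
    crossed = np.zeros(n, dtype=bool)

    def after_fraction(k: int, st) -> bool:
        nonlocal s_prev
        s = cf * np.asarray(st.total_viable, dtype=float)
        newly = (~crossed) & (s <= _LN2)
        n_low[newly] = k - 1
        s_low[newly] = s_prev[newly]
        s_high[newly] = s[newly]
        crossed[newly] = True
        s_prev = np.where(crossed, s_prev, s)
        return bool(crossed.all())

    run_course(state, params, max_fractions, after_fraction=after_fraction)
    if not crossed.all():
        bad = np.flatnonzero(~crossed)
        pairs = [(float(np.asarray(gf)[i]), float(np.asarray(clf)[i])) for i in bad[:5]]
        raise RuntimeError(
            f"TCP = 0.5 not reached within {max_fractions} fractions for "
            f"{bad.size} scenario(s), e.g. (gf, clf) = {pairs}"
        )
    return n_low, s_low, s_high


def find_td50(
    scenario: Scenario, params: TumorletParams, max_fractions: int = 200
) -> TD50Result:
    """TD50 for a single scenario.

    Scans fraction counts forward (each course prefix shares its
    trajectory with all longer courses, so one simulation suffices) and
    interpolates the ln 2 crossing of the clonogen survival curve.
    """
    gf = np.asarray([scenario.gf])
    clf = np.asarray([scenario.clf])
    try:
        n_low, s_low, s_high = _survival_brackets(gf, clf, params, max_fractions)
    except RuntimeError as exc:
        raise RuntimeError(
            f"scenario (gf={scenario.gf}, clf={scenario.clf}): {exc}"
        ) from exc
    td50 = interpolate_td50(n_low, s_low, s_high, params.fraction_dose)
    return TD50Result(
        gf=scenario.gf,
        clf=scenario.clf,
        td50=float(td50[0]),
        n_low=int(n_low[0]),
        n_high=int(n_low[0]) + 1,
        tcp_low=float(poisson_tcp(float(s_low[0]))),
        tcp_high=float(poisson_tcp(float(s_high[0]))),
    )


def td50_sweep(
    gf: np.ndarray,
    clf: np.ndarray,
    params: TumorletParams,
    max_fractions: int = 200,
) -> np.ndarray:
    """Vectorized TD50 (Gy) for arrays of (gf, clf) scenarios.

    All scenarios are advanced through one shared course in lockstep;
    each scenario's crossing is interpolated independently.
    """
    n_low, s_low, s_high = _survival_brackets(
        np.asarray(gf, float), np.asarray(clf, float), params, max_fractions
    )
    return np.asarray(interpolate_td50(n_low, s_low, s_high, params.fraction_dose))
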