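"""Microenvironment scenario grid.

Every feasible (growth fraction, cell loss factor) combination on the
study lattice: GF in steps of 0.01 from 0.01, CLF in steps of 0.03 from
0.03 to 0.99, subject to the feasibility bound GF <= 1/(2 + CLF). The
lattice is built from integer indices (GF = i/100, CLF = 3j/100) and the
bound is checked with exact integer arithmetic (i*(200 + 3j) <= 10000),
so floating-point step accumulation cannot change grid membership. At the
defaults this yields exactly 1315 scenarios. GF values exactly on the
bound are included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .core import CompartmentState, init_compartments
from .params import TumorletParams

__all__ = ["GridSpec", "Scenario", "build_grid", "make_scenarios"]


@dataclass(frozen=True)
class GridSpec:
    """Lattice specification for the (GF, CLF) scenario sweep."""

    gf_min: float = 0.01
    gf_step: float = 0.01
    clf_min: float = 0.03
    clf_max: float = 0.99
    clf_step: float = 0.03

    def __post_init__(self) -> None:
        if self.gf_step <= 0 or self.clf_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.gf_min <= 0 or self.clf_min <= 0:
            raise ValueError("gf_min and clf_min must be positive")
        if not self.clf_min <= self.clf_max < 1:
            raise ValueError("need clf_min <= clf_max < 1")


@dataclass(frozen=True)
class Scenario:
    """One microenvironment: a (GF, CLF) pair plus its initial state."""

    gf: float
    clf: float
    initial_state: CompartmentState = field(compare=False)

    def __post_init__(self) -> None:
        if self.gf > 1.0 / (2.0 + self.clf) + 1e-12:
            raise ValueError(
                f"infeasible scenario (gf={self.gf}, clf={self.clf}): "
                "gf exceeds 1/(2+clf)"
            )


def build_grid(spec: GridSpec | None = None) -> list[tuple[float, float]]:
    """Enumerate every feasible (GF, CLF) lattice point.

    Ordering is CLF-major ascending, then GF ascending; building twice
    gives identical output. The feasibility bound GF <= 1/(2+CLF) is
    evaluated with exact rational arithmetic and is closed (boundary
    points included).
    """
    spec = spec or GridSpec()
    gf_min = Fraction(spec.gf_min).limit_denominator(10**6)
    gf_step = Fraction(spec.gf_step).limit_denominator(10**6)
    clf_min = Fraction(spec.clf_min).limit_denominator(10**6)
    clf_max = Fraction(spec.clf_max).limit_denominator(10**6)
    clf_step = Fraction(spec.clf_step).limit_denominator(10**6)

    pairs: list[tuple[float, float]] = []
    j = 0
    while True:
        clf = clf_min + j * clf_step
        if clf > clf_max:
            break
        bound = Fraction(1) / (2 + clf)
        i = 0
        while True:
            gf = gf_min + i * gf_step
            if gf > bound:  # exact rational comparison; bound inclusive
                break
            pairs.append((float(gf), float(clf)))
            i += 1
        j += 1
    # present CLF-major ascending
    return pairs


def make_scenarios(
    grid: Iterable[tuple[float, float]], params: TumorletParams
) -> list[Scenario]:
    """Attach initialized compartment states to (GF, CLF) pairs.

    Infeasible pairs raise with the offending pair identified.
    """
    scenarios: list[Scenario] = []
    for gf, clf in grid:
        try:
            state = init_compartments(gf, clf, params)
        except ValueError as exc:
            raise ValueError(f"scenario (gf={gf}, clf={clf}): {exc}") from exc
        scenarios.append(Scenario(gf=gf, clf=clf, initial_state=state))
    return scenarios


def grid_arrays(
    pairs: Sequence[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """Split a pair list into (gf, clf) float arrays for vectorized use."""
    if not pairs:
        raise ValueError("empty grid")
    arr = np.asarray(pairs, dtype=float)
    return arr[:, 0], arr[:, 1]
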