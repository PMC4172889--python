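"""Compartment state and the elementary radiobiology of the tumorlet.

A tumorlet is a well-mixed PET-voxel-sized tumor subvolume whose cells are
split by microenvironment into three compartments:

* ``P`` — oxygen and glucose available; the only proliferating cells.
* ``I`` — glucose but no oxygen; metabolically active, non-proliferating,
  hypoxic (radioresistant, OER = 2).
* ``H`` — neither oxygen nor glucose; starving and dying (OER = 1.37,
  reflecting reduced repair capability under extreme stress).

Irradiated cells that fail to survive the linear-quadratic lottery become
*doomed*: metabolically alive, occupying capacity, but destined to die at
a subsequent mitosis. All counts are expected values (continuous cells).

Every function in this module is written against either scalar floats or
equal-shaped numpy arrays, so one implementation serves both the
single-scenario simulator and the vectorized whole-grid sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Union

import numpy as np

from .params import TumorletParams

__all__ = [
    "CompartmentState",
    "init_compartments",
    "lq_surviving_fraction",
    "proliferating_fraction",
]

ArrayLike = Union[float, np.ndarray]

#: relative tolerance for capacity / non-negativity checks
_RTOL = 1e-9


@dataclass
class CompartmentState:
    """Viable and doomed expected cell counts per compartment.

    ``cap_p`` and ``cap_i`` are the fixed carrying capacities of the P- and
    I-compartments (the blood supply is locally constant over the course of
    treatment, so the capacities are frozen at the initial viable counts).
    The H-compartment is unbounded. Doomed cells occupy capacity exactly
    like viable cells: they remain metabolically alive until mitotic death,
    which is what lets their eventual death drive reoxygenation.
    """

    viable_p: ArrayLike
    doomed_p: ArrayLike
    viable_i: ArrayLike
    doomed_i: ArrayLike
    viable_h: ArrayLike
    doomed_h: ArrayLike
    cap_p: ArrayLike
    cap_i: ArrayLike

    def copy(self) -> "CompartmentState":
        return replace(
            self,
            **{
                f: np.array(getattr(self, f), dtype=float, copy=True)
                if isinstance(getattr(self, f), np.ndarray)
                else getattr(self, f)
                for f in (
                    "viable_p",
                    "doomed_p",
                    "viable_i",
                    "doomed_i",
                    "viable_h",
                    "doomed_h",
                    "cap_p",
                    "cap_i",
                )
            },
        )

    @property
    def total_viable(self) -> ArrayLike:
        return self.viable_p + self.viable_i + self.viable_h

    @property
    def total(self) -> ArrayLike:
        return (
            self.viable_p
            + self.doomed_p
            + self.viable_i
            + self.doomed_i
            + self.viable_h
            + self.doomed_h
        )

    @property
    def occupants_p(self) -> ArrayLike:
        return self.viable_p + self.doomed_p

    @property
    def occupants_i(self) -> ArrayLike:
        return self.viable_i + self.doomed_i

    def validate(self) -> None:
        """Raise ``ValueError`` on negative counts or capacity violations."""
        scale = np.maximum(np.asarray(self.total, dtype=float), 1.0)
        for name in ("viable_p", "doomed_p", "viable_i", "doomed_i", "viable_h", "doomed_h"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < -_RTOL * scale):
                raise ValueError(f"negative cell count in {name}")
        tol_p = _RTOL * np.maximum(np.asarray(self.cap_p, dtype=float), 1.0)
        tol_i = _RTOL * np.maximum(np.asarray(self.cap_i, dtype=float), 1.0)
        if np.any(np.asarray(self.occupants_p) > np.asarray(self.cap_p) + tol_p):
            raise ValueError("P-compartment over capacity")
        if np.any(np.asarray(self.occupants_i) > np.asarray(self.cap_i) + tol_i):
            raise ValueError("I-compartment over capacity")


def init_compartments(
    gf: ArrayLike, clf: ArrayLike, params: TumorletParams
) -> CompartmentState:
    """Initial cell distribution for a microenvironment (GF, CLF).

    With ``N0 = volume * cell_density``:

    * ``N_P = GF * N0`` — the growth fraction is, by definition, the
      proliferating share of the population;
    * ``N_H = CLF * GF * N0`` — the starving compartment grows with the
      cell loss factor (loss rate relative to production, which scales
      with N_P);
    * ``N_I = N0 - N_P - N_H`` — the remainder.

    Feasibility requires ``GF <= 1/(2 + CLF)``, which is algebraically
    equivalent to ``N_I >= N_P``. Capacities are frozen at the initial
    viable counts; no doomed cells exist before treatment.
    """
    gf = np.asarray(gf, dtype=float) if isinstance(gf, np.ndarray) else float(gf)
    clf = np.asarray(clf, dtype=float) if isinstance(clf, np.ndarray) else float(clf)
    bound = 1.0 / (2.0 + clf)
    if np.any(np.asarray(gf) < 0) or np.any(np.asarray(clf) < 0) or np.any(np.asarray(clf) >= 1):
        raise ValueError("need gf >= 0 and 0 <= clf < 1")
    if np.any(np.asarray(gf) > np.asarray(bound) * (1 + 1e-12)):
        raise ValueError(
            f"infeasible scenario: gf={gf!r} exceeds 1/(2+clf) for clf={clf!r} "
            "(the I-compartment would fall below the P-compartment)"
        )
    n0 = params.n_cells
    viable_p = gf * n0
    viable_h = clf * gf * n0
    viable_i = n0 - viable_p - viable_h
    zero = np.zeros_like(viable_p) if isinstance(viable_p, np.ndarray) else 0.0
    return CompartmentState(
        viable_p=viable_p,
        doomed_p=zero if isinstance(viable_p, np.ndarray) else 0.0,
        viable_i=viable_i,
        doomed_i=zero.copy() if isinstance(viable_p, np.ndarray) else 0.0,
        viable_h=viable_h,
        doomed_h=zero.copy() if isinstance(viable_p, np.ndarray) else 0.0,
        cap_p=viable_p + 0.0,
        cap_i=viable_i + 0.0,
    )


def lq_surviving_fraction(
    dose: ArrayLike, oer: ArrayLike, params: TumorletParams
) -> ArrayLike:
    """Linear-quadratic surviving fraction with OER as dose modifier.

    ``SF = exp(-(alpha * d_eff + beta * d_eff^2))`` with
    ``d_eff = dose / OER``, ``alpha = alpha_p`` and
    ``beta = alpha_p / (alpha/beta)``.
    """
    if np.any(np.asarray(dose) < 0):
        raise ValueError("dose must be non-negative")
    if np.any(np.asarray(oer) < 1):
        raise ValueError("OER must be >= 1")
    d_eff = dose / oer
    return np.exp(-(params.alpha_p * d_eff + params.beta_p * d_eff**2))


def proliferating_fraction(
    occupancy: ArrayLike, frac_low: float = 1.0, frac_full: float = 0.5
) -> ArrayLike:
    """Fraction of P-cells in cycle as a function of P occupancy.

    Density inhibition: ``frac_low`` (default 100%) of cells proliferate
    while the compartment is at or below half capacity, ``frac_full``
    (default 50%) when it is full, with linear interpolation in between.
    """
    occ = np.asarray(occupancy, dtype=float)
    if np.any(occ < -1e-12) or np.any(occ > 1.0 + 1e-9):
        raise ValueError(f"P occupancy outside [0, 1]: {occupancy!r}")
    occ = np.clip(occ, 0.0, 1.0)
    out = np.where(
        occ <= 0.5, frac_low, frac_low + (occ - 0.5) * 2.0 * (frac_full - frac_low)
    )
    return float(out) if out.ndim == 0 else out
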