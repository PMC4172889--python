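"""Biological and physical parameters of the tumorlet model.

The parameter set is the head-and-neck squamous-cell-carcinoma (HNSCC)
configuration: a PET-voxel-sized tumorlet (64 mm^3 at 10^6 cells/mm^3),
linear-quadratic radiosensitivity of the oxygenated proliferating
compartment (alpha_p = 0.382 / Gy, alpha/beta = 6.63 Gy), oxygen
enhancement ratios of 1 / 2 / 1.37 for the P / I / H compartments, and a
standard 2 Gy-per-fraction, five-fractions-per-week schedule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["TumorletParams", "load_config"]


@dataclass(frozen=True)
class TumorletParams:
    """All tunable constants of the tumorlet simulation.

    Attributes
    ----------
    volume : float
        Tumorlet volume in mm^3 (one PET voxel, 4 x 4 x 4 mm).
    cell_density : float
        Tumor cell density in cells per mm^3.
    clonogenic_fraction : float
        Fraction of viable cells with unlimited regrowth potential
        (clonogens); only these enter the Poisson TCP.
    alpha_p : float
        Linear-quadratic alpha of the well-oxygenated P-compartment, 1/Gy.
    alpha_beta_ratio : float
        alpha/beta in Gy; beta is derived as ``alpha_p / alpha_beta_ratio``
        and shared across compartments before OER modification.
    oer_p, oer_i, oer_h : float
        Oxygen enhancement ratios, applied as dose-modifying factors
        (effective dose = dose / OER in both LQ terms).
    fraction_dose : float
        Dose per fraction, Gy.
    fractions_per_week : int
        Fractions delivered per week (Mon-Fri pattern).
    progeny_survival : float
        Probability that each of the two progeny of a doomed cell's
        mitosis survives (as another doomed cell).
    h_loss_half_time : float
        Starvation cell-loss half-time in the H-compartment, days.
    cell_cycle_time : float
        Doubling interval of an individual proliferating cell, days.
    dt : float
        Simulation time step, hours; must divide 24 evenly.
    prolif_frac_full : float
        Proliferating fraction of P-cells when P is at capacity.
    prolif_frac_low : float
        Proliferating fraction when P occupancy is at or below one half.
    """

    volume: float = 64.0
    cell_density: float = 1e6
    clonogenic_fraction: float = 0.01
    alpha_p: float = 0.382
    alpha_beta_ratio: float = 6.63
    oer_p: float = 1.0
    oer_i: float = 2.0
    oer_h: float = 1.37
    fraction_dose: float = 2.0
    fractions_per_week: int = 5
    progeny_survival: float = 0.3
    h_loss_half_time: float = 2.0
    cell_cycle_time: float = 2.0
    dt: float = 1.0
    prolif_frac_full: float = 0.5
    prolif_frac_low: float = 1.0

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.cell_density <= 0:
            raise ValueError("volume and cell_density must be positive")
        if not 0 < self.clonogenic_fraction <= 1:
            raise ValueError("clonogenic_fraction must lie in (0, 1]")
        if self.alpha_p <= 0 or self.alpha_beta_ratio <= 0:
            raise ValueError("alpha_p and alpha_beta_ratio must be positive")
        for name in ("oer_p", "oer_i", "oer_h"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fraction_dose < 0:
            raise ValueError("fraction_dose must be non-negative")
        if self.fractions_per_week < 1 or self.fractions_per_week > 7:
            raise ValueError("fractions_per_week must be in 1..7")
        if not 0 <= self.progeny_survival <= 1:
            raise ValueError("progeny_survival must lie in [0, 1]")
        if self.h_loss_half_time <= 0 or self.cell_cycle_time <= 0:
            raise ValueError("kinetic time constants must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if abs(24.0 / self.dt - round(24.0 / self.dt)) > 1e-9:
            raise ValueError("dt (hours) must divide 24 evenly")
        if not 0 < self.prolif_frac_full <= self.prolif_frac_low <= 1:
            raise ValueError("need 0 < prolif_frac_full <= prolif_frac_low <= 1")

    @property
    def beta_p(self) -> float:
        """LQ beta of the P-compartment, 1/Gy^2."""
        return self.alpha_p / self.alpha_beta_ratio

    @property
    def n_cells(self) -> float:
        """Total initial cell number N0 = volume * density."""
        return self.volume * self.cell_density

    def replace(self, **changes: Any) -> "TumorletParams":
        """Return a copy with the given fields overridden."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML or JSON config file with optional ``params:`` and
    ``grid:`` sections; unknown keys raise.

    Returns a dict with keys ``params`` (TumorletParams) and ``grid``
    (dict of GridSpec overrides, possibly empty).
    """
    path = Path(path)
    text = path.read_text()
    data: Mapping[str, Any]
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    unknown = set(data) - {"params", "grid"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    param_over = dict(data.get("params") or {})
    valid = {f.name for f in dataclasses.fields(TumorletParams)}
    bad = set(param_over) - valid
    if bad:
        raise ValueError(f"unknown parameter names: {sorted(bad)}")
    return {
        "params": TumorletParams(**param_over),
        "grid": dict(data.get("grid") or {}),
    }
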