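"""Hypothetical baseline FDG uptake patterns.

Four hypotheses about how FDG (glucose) uptake distributes over the
compartments, expressed as relative per-cell uptake weights P : I : H:

* **I**   1 : 1 : 0 — uptake proportional to the metabolically viable
  cells (P and I alike; starving H-cells take up nothing),
* **II**  3 : 1 : 0 — uptake dominated by proliferating cells,
* **III** 1 : 3 : 0 — uptake dominated by the glucose-only hypoxic cells,
* **IV**  2 : 5 : 2 — as III with a reduced contribution from the
  starving H-compartment.

Uptake is scored on the pre-treatment state (no doomed cells exist) and
normalized to the maximum over the scenario grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ArrayLike, CompartmentState

__all__ = ["UptakePattern", "PATTERNS", "get_pattern", "uptake", "normalize_uptake"]


@dataclass(frozen=True)
class UptakePattern:
    """Relative per-cell FDG uptake weights (w_p, w_i, w_h)."""

    name: str
    weights: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("uptake weights must be non-negative")


PATTERNS: dict[str, UptakePattern] = {
    "I": UptakePattern("I", (1.0, 1.0, 0.0)),
    "II": UptakePattern("II", (3.0, 1.0, 0.0)),
    "III": UptakePattern("III", (1.0, 3.0, 0.0)),
    "IV": UptakePattern("IV", (2.0, 5.0, 2.0)),
}


def get_pattern(name: str) -> UptakePattern:
    try:
        return PATTERNS[name]
    except KeyError:
        raise ValueError(
            f"unknown uptake pattern {name!r}; choose from {sorted(PATTERNS)}"
        ) from None


def uptake(state: CompartmentState, pattern: UptakePattern | str) -> ArrayLike:
    """Baseline uptake score: weighted sum of viable compartment counts."""
    if isinstance(pattern, str):
        pattern = get_pattern(pattern)
    w_p, w_i, w_h = pattern.weights
    score = w_p * state.viable_p + w_i * state.viable_i + w_h * state.viable_h
    return float(score) if np.asarray(score).ndim == 0 else score


def normalize_uptake(scores: ArrayLike) -> np.ndarray:
    """Scale a grid of uptake scores so the maximum is exactly 1."""
    arr = np.asarray(scores, dtype=float)
    peak = arr.max() if arr.size else 0.0
    if not peak > 0:
        raise ValueError("cannot normalize: no positive uptake score")
    return arr / peak
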