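"""Grid-level analysis: uptake-vs-radioresistance correlations.

Assembles the per-scenario results table (GF, CLF, initial compartment
counts, TD50, raw and normalized uptake per pattern) and computes the
study's summary statistics: squared Pearson correlation (R^2) of each
uptake pattern against TD50, compartment-count correlations, the
high-vs-low-uptake TD50 ratio, the fixed-CLF binned view, and the
OER_H sensitivity sweep. R^2 is computed on the raw scenario points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import init_compartments
from .grid import GridSpec, build_grid, grid_arrays
from .params import TumorletParams
from .tcp import td50_sweep
from .uptake import PATTERNS, UptakePattern, get_pattern, normalize_uptake, uptake

__all__ = [
    "CorrelationReport",
    "run_pipeline",
    "pearson_r2",
    "correlate_patterns",
    "correlate_compartments",
    "high_low_td50_ratio",
    "fixed_clf_analysis",
    "oer_sensitivity",
]


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation of one covariate against TD50."""

    name: str
    r: float
    r2: float
    n: int

    @property
    def slope_sign(self) -> int:
        return int(np.sign(self.r))


def pearson_r2(x: np.ndarray, y: np.ndarray, name: str = "") -> CorrelationReport:
    """Pearson r and r^2 between two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationReport(name=name, r=r, r2=r * r, n=x.size)


def run_pipeline(
    params: TumorletParams | None = None,
    grid_spec: GridSpec | None = None,
    patterns: tuple[str, ...] = ("I", "II", "III", "IV"),
    max_fractions: int = 200,
) -> pd.DataFrame:
    """Grid -> initial states -> TD50 sweep -> uptake scores.

    Returns one row per scenario with columns ``scenario_id, gf, clf,
    n_p0, n_i0, n_h0, n_low, td50_gy`` plus ``uptake_<p>`` and
    ``uptake_<p>_norm`` for each requested pattern.
    """
    params = params or TumorletParams()
    pairs = build_grid(grid_spec or GridSpec())
    gf, clf = grid_arrays(pairs)
    state0 = init_compartments(gf, clf, params)
    td50 = td50_sweep(gf, clf, params, max_fractions=max_fractions)
    df = pd.DataFrame(
        {
            "scenario_id": np.arange(gf.size),
            "gf": gf,
            "clf": clf,
            "n_p0": np.asarray(state0.viable_p),
            "n_i0": np.asarray(state0.viable_i),
            "n_h0": np.asarray(state0.viable_h),
            "td50_gy": td50,
        }
    )
    for name in patterns:
        raw = np.asarray(uptake(state0, get_pattern(name)))
        df[f"uptake_{name}"] = raw
        df[f"uptake_{name}_norm"] = normalize_uptake(raw)
    return df


def correlate_patterns(
    grid_result: pd.DataFrame, patterns: tuple[str, ...] = ("I", "II", "III", "IV")
) -> dict[str, CorrelationReport]:
    """R^2 of normalized uptake vs TD50, one report per pattern."""
    return {
        name: pearson_r2(
            grid_result[f"uptake_{name}_norm"].to_numpy(),
            grid_result["td50_gy"].to_numpy(),
            name=f"pattern {name}",
        )
        for name in patterns
    }


def correlate_compartments(grid_result: pd.DataFrame) -> dict[str, CorrelationReport]:
    """R^2 of the initial I- and H-compartment counts vs TD50."""
    td50 = grid_result["td50_gy"].to_numpy()
    return {
        "I": pearson_r2(grid_result["n_i0"].to_numpy(), td50, name="N_I"),
        "H": pearson_r2(grid_result["n_h0"].to_numpy(), td50, name="N_H"),
    }


def high_low_td50_ratio(
    grid_result: pd.DataFrame, pattern: UptakePattern | str = "III"
) -> float:
    """Ratio of mean TD50, high- vs low-uptake half of the grid.

    Scenarios are split at the median normalized uptake for the pattern;
    ties go to the low group, except that with an odd scenario count a
    single exactly-median row is dropped to balance the halves.
    """
    name = pattern if isinstance(pattern, str) else pattern.name
    u = grid_result[f"uptake_{name}_norm"].to_numpy()
    td50 = grid_result["td50_gy"].to_numpy()
    med = float(np.median(u))
    high = u > med
    low = u < med
    at_median = u == med
    if u.size % 2 == 1 and at_median.sum() == 1:
        pass  # drop the single median row
    else:
        low = low | at_median
    if not high.any() or not low.any():
        raise ValueError("median split produced an empty group")
    return float(td50[high].mean() / td50[low].mean())


def fixed_clf_analysis(
    grid_result: pd.DataFrame,
    clf: float = 0.9,
    pattern: UptakePattern | str = "IV",
    n_bins: int = 5,
) -> pd.DataFrame:
    """Binned uptake-vs-TD50 view at one fixed cell loss factor.

    Subsets the grid to the given CLF, bins scenarios into ``n_bins``
    equal-count bins of ascending normalized uptake, and reports per bin
    the TD50 quartiles and the median growth fraction. Under patterns
    where hypoxic cells dominate uptake, the median GF decreases as
    uptake rises.
    """
    name = pattern if isinstance(pattern, str) else pattern.name
    sub = grid_result[np.isclose(grid_result["clf"], clf, atol=1e-9)].copy()
    if sub.empty:
        raise ValueError(f"no scenarios at clf={clf}")
    n_bins = min(n_bins, len(sub))
    sub = sub.sort_values(f"uptake_{name}_norm").reset_index(drop=True)
    sub["bin"] = pd.qcut(sub[f"uptake_{name}_norm"], q=n_bins, labels=False, duplicates="drop")
    rows = []
    for b, g in sub.groupby("bin", sort=True):
        rows.append(
            {
                "bin": int(b),
                "n": len(g),
                "uptake_min": g[f"uptake_{name}_norm"].min(),
                "uptake_max": g[f"uptake_{name}_norm"].max(),
                "td50_q25": g["td50_gy"].quantile(0.25),
                "td50_median": g["td50_gy"].median(),
                "td50_q75": g["td50_gy"].quantile(0.75),
                "median_gf": g["gf"].median(),
            }
        )
    return pd.DataFrame(rows)


def oer_sensitivity(
    params: TumorletParams | None = None,
    grid_spec: GridSpec | None = None,
    oer_h_values: tuple[float, ...] = (1.37, 2.0, 3.0),
    max_fractions: int = 200,
) -> dict[float, CorrelationReport]:
    """N_I-vs-TD50 correlation as the H-compartment OER is raised.

    The full TD50 sweep is recomputed for each OER_H variant; only the
    H-compartment radiosensitivity changes.
    """
    params = params or TumorletParams()
    pairs = build_grid(grid_spec or GridSpec())
    gf, clf = grid_arrays(pairs)
    n_i0 = np.asarray(init_compartments(gf, clf, params).viable_i)
    out: dict[float, CorrelationReport] = {}
    for oer_h in oer_h_values:
        td50 = td50_sweep(gf, clf, params.replace(oer_h=oer_h), max_fractions)
        out[oer_h] = pearson_r2(n_i0, td50, name=f"N_I (OER_H={oer_h})")
    return out
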