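"""Descriptive adequacy surfaces.

Percent-of-requirement and percent-gap relative to the NNRD, nutrient density
per 2000 kcal, min-max normalization for cross-nutrient display, gap binning
for choropleth-style classification, IQR-based exclusion of implausible
country-years, and paired-series comparison statistics (Pearson/Spearman
correlations and elementwise percent differences) for benchmarking against
external estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

# Gap bins: 10 classes symmetric about zero; 8 interior half-open bins of
# width 15 pp with open tails below -60 and at/above +60.
GAP_BIN_EDGES = tuple(float(e) for e in range(-60, 75, 15))  # -60 .. +60
N_GAP_BINS = len(GAP_BIN_EDGES) + 1  # 10


def percent_of_requirement(pc_value: float, pc_requirement: float) -> float:
    """Per-capita supply as a percent of the weighted per-capita requirement."""
    if pc_requirement <= 0:
        raise ValueError("requirement must be positive")
    return 100.0 * pc_value / pc_requirement


def percent_gap(pc_value: float, pc_requirement: float) -> float:
    """Percent difference between supply and requirement (negative = deficit)."""
    return percent_of_requirement(pc_value, pc_requirement) - 100.0


def nutrient_density(pc_value: float, pc_energy_kcal: float) -> float:
    """Nutrient amount per 2000 kcal of dietary energy."""
    if pc_energy_kcal <= 0:
        warnings.warn("non-positive energy; density undefined")
        return float("nan")
    return pc_value / pc_energy_kcal * 2000.0


def minmax_normalize(values) -> np.ndarray:
    """Affine map of a pooled series onto [0, 100].

    Applied per nutrient and per side (production vs apparent intake) with
    all years pooled, so the two years of a comparison share a scale.  A
    constant series maps to all zeros with a warning.
    """
    arr = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(arr), np.nanmax(arr)
    if hi == lo:
        warnings.warn("constant series; normalization returns zeros")
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo) * 100.0


def bin_gap(gap_pct: float) -> int:
    """Assign a percent gap to one of 10 ordered classes (1..10).

    Interior bins are half-open ``[lower, upper)`` and 15 percentage points
    wide with edges at -60, -45, ..., +60; bins 1 and 10 are the open tails.
    """
    if not np.isfinite(gap_pct):
        raise ValueError("gap must be finite")
    return int(np.searchsorted(GAP_BIN_EDGES, gap_pct, side="right")) + 1


def gap_bin_bounds(bin_index: int) -> tuple[float, float]:
    """(lower, upper) bounds of a gap class; open tails are infinite."""
    if not 1 <= bin_index <= N_GAP_BINS:
        raise ValueError(f"bin index out of range 1..{N_GAP_BINS}")
    edges = (-np.inf,) + GAP_BIN_EDGES + (np.inf,)
    return edges[bin_index - 1], edges[bin_index]


def iqr_exclude(
    energy: pd.Series, k: float = 1.5, min_obs: int = 4
) -> pd.Series:
    """Flag implausible observations by Tukey fences on per-capita energy.

    Flags values outside ``[Q1 - k*IQR, Q3 + k*IQR]``.  With fewer than
    ``min_obs`` observations no flags are raised (warning).  The fence scope
    (pooled vs per-year) is the caller's choice of what to pass in.
    """
    s = pd.Series(energy, dtype=float)
    if len(s.dropna()) < min_obs:
        warnings.warn(f"fewer than {min_obs} observations; no exclusions")
        return pd.Series(False, index=s.index)
    q1, q3 = s.quantile(0.25), s.quantile(0.75)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (s < lo) | (s > hi)


def compare_series(x, y) -> dict:
    """Pearson/Spearman correlations and elementwise percent differences.

    Percent difference is ``(x - y)/y * 100`` per element (e.g. engine
    estimate vs external benchmark).  Zero-variance inputs yield NaN
    correlations.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("paired series must have equal length")
    if len(xa) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("paired series must be finite")

    if np.std(xa) == 0 or np.std(ya) == 0:
        pearson = spearman = (float("nan"), float("nan"))
    else:
        pr = sps.pearsonr(xa, ya)
        sr = sps.spearmanr(xa, ya)
        pearson = (float(pr.statistic), float(pr.pvalue))
        spearman = (float(sr.statistic), float(sr.pvalue))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_diff = np.where(ya != 0, (xa - ya) / ya * 100.0, np.nan)
    return {
        "pearson_r": pearson[0],
        "pearson_p": pearson[1],
        "spearman_rho": spearman[0],
        "spearman_p": spearman[1],
        "percent_difference": pct_diff,
    }


def adequacy_table(
    totals: pd.DataFrame, nnrd: pd.DataFrame, side: str
) -> pd.DataFrame:
    """Join country-year nutrient totals with the NNRD.

    ``totals`` has columns ``country, year, nutrient, value`` (one variant,
    one side); ``nnrd`` columns ``country, year, nutrient, requirement``.

    Returns columns ``country, year, nutrient, side, pc_value,
    pc_requirement, percent_of_requirement, percent_gap, gap_bin``.
    """
    merged = totals.merge(nnrd, on=["country", "year", "nutrient"], how="inner")
    if (merged["requirement"] <= 0).any():
        raise ValueError("requirements must be positive")
    merged = merged.rename(columns={"value": "pc_value", "requirement": "pc_requirement"})
    merged["side"] = side
    merged["percent_of_requirement"] = (
        100.0 * merged["pc_value"] / merged["pc_requirement"]
    )
    merged["percent_gap"] = merged["percent_of_requirement"] - 100.0
    merged["gap_bin"] = merged["percent_gap"].map(bin_gap)
    cols = [
        "country",
        "year",
        "nutrient",
        "side",
        "pc_value",
        "pc_requirement",
        "percent_of_requirement",
        "percent_gap",
        "gap_bin",
    ]
    return merged[cols]
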