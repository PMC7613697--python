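"""Monte Carlo sensitivity of nutrient totals to catch-all category composition.

The "other / not elsewhere specified" food categories (FCOs) pool many
distinct items, so their composition is uncertain.  Each Monte Carlo draw
assigns every FCO a random convex combination of its candidate item
compositions (symmetric Dirichlet(1,...,1) weights, uniform over the
simplex), recomputes the global per-capita totals, and summarises the spread
as a percent deviation from the baseline in which every FCO uses the mean of
its candidates (the same collapse rule as the main composition table).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class McResult:
    """Distribution summary of one nutrient's global total across draws."""

    nutrient: str
    baseline: float
    minimum: float
    maximum: float
    median: float
    half_range_pct: float  # (max - min) / 2 as % of baseline (NaN if baseline 0)
    exceeds_5pct: bool


def _totals(
    weights_by_fco: Mapping[str, np.ndarray],
    candidates: Mapping[str, pd.DataFrame],
    fco_mass_g_day: Mapping[str, float],
    base_totals: pd.Series,
) -> pd.Series:
    total = base_totals.astype(float).copy()
    for fco, cand in candidates.items():
        w = weights_by_fco[fco]
        comp = pd.Series(w @ cand.to_numpy(), index=cand.columns)
        total = total.add(fco_mass_g_day[fco] * comp / 100.0, fill_value=0.0)
    return total


def sample_fco_totals(
    candidates: Mapping[str, pd.DataFrame],
    fco_mass_g_day: Mapping[str, float],
    base_totals: pd.Series | Mapping[str, float],
    n_draws: int = 1000,
    seed: int = 0,
    threshold_pct: float = 5.0,
) -> list[McResult]:
    """Monte Carlo spread of global nutrient totals over FCO compositions.

    Parameters
    ----------
    candidates
        Per FCO, a DataFrame of candidate item compositions (rows = items,
        columns = nutrients, per 100 g edible portion).
    fco_mass_g_day
        Global per-capita edible mass (g/day) flowing through each FCO.
    base_totals
        Per-nutrient totals contributed by all non-FCO categories.
    n_draws, seed
        Number of Dirichlet draws and RNG seed (fixed seed → identical
        results).
    threshold_pct
        Half-range percent above which a nutrient is flagged.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    for fco, cand in candidates.items():
        if len(cand) == 0:
            raise ValueError(f"FCO {fco!r} has an empty candidate set")
    base = pd.Series(base_totals, dtype=float)
    rng = np.random.default_rng(seed)

    mean_weights = {
        fco: np.full(len(cand), 1.0 / len(cand)) for fco, cand in candidates.items()
    }
    baseline = _totals(mean_weights, candidates, fco_mass_g_day, base)

    draws = np.empty((n_draws, len(baseline)))
    for i in range(n_draws):
        weights = {
            fco: rng.dirichlet(np.ones(len(cand)))
            for fco, cand in candidates.items()
        }
        draws[i] = _totals(weights, candidates, fco_mass_g_day, base).to_numpy()

    results = []
    for j, nutrient in enumerate(baseline.index):
        col = draws[:, j]
        b = float(baseline.iloc[j])
        half_range = (col.max() - col.min()) / 2.0
        pct = float("nan") if b == 0 else 100.0 * half_range / b
        results.append(
            McResult(
                nutrient=nutrient,
                baseline=b,
                minimum=float(col.min()),
                maximum=float(col.max()),
                median=float(np.median(col)),
                half_range_pct=pct,
                exceeds_5pct=bool(pct > threshold_pct) if b != 0 else False,
            )
        )
    return results


def vertex_totals(
    candidates: Mapping[str, pd.DataFrame],
    fco_mass_g_day: Mapping[str, float],
    base_totals: pd.Series | Mapping[str, float],
) -> pd.DataFrame:
    """Totals at every vertex assignment (one candidate per FCO).

    Exhaustive enumeration of the simplex vertices; the convex-hull bound for
    any Dirichlet draw.  Intended for small FCO/candidate sets in tests.
    """
    base = pd.Series(base_totals, dtype=float)
    fcos = list(candidates)
    index_sets = [range(len(candidates[f])) for f in fcos]
    rows = []
    for combo in itertools.product(*index_sets):
        weights = {}
        for f, idx in zip(fcos, combo):
            w = np.zeros(len(candidates[f]))
            w[idx] = 1.0
            weights[f] = w
        rows.append(_totals(weights, candidates, fco_mass_g_day, base))
    return pd.DataFrame(rows)


def mc_report(results: Sequence[McResult]) -> pd.DataFrame:
    """Monte Carlo results as a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "nutrient": r.nutrient,
                "baseline": r.baseline,
                "min": r.minimum,
                "median": r.median,
                "max": r.maximum,
                "half_range_pct": r.half_range_pct,
                "exceeds_5pct": r.exceeds_5pct,
            }
            for r in results
        ]
    )
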