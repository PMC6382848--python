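"""Masking, biome identification and rainfall-range assignment.

Builds the analysis table from per-cell land-cover class fractions,
vegetation cover and the derived climate/fire metrics:

* cells dominated by shrubland (fraction > 0.5) are removed, because the
  tree-cover product underestimates trees among shrubs;
* cells with more than a third of their area influenced by humans, covered
  by water, or under permanent snow/ice (combined) are removed;
* tropical grassy biome (TGB) cells are those with more than half their
  area mapped as deciduous trees or grassland;
* surviving cells are labelled by mean-annual-rainfall range: R1 (MAR ≤ 630
  mm/y), R2 (630 < MAR < 1200), R3 (1200 ≤ MAR ≤ 2500); wetter cells are
  excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LANDCOVER_COLUMNS",
    "MaskLog",
    "apply_masks",
    "identify_tgb",
    "assign_mar_range",
    "build_analysis_table",
    "compare_medians",
]

#: Land-cover fraction columns expected on input tables.
LC_SHRUB = "frac_shrubland"
LC_DISTURBED = "frac_human_water"  # cropland/urban + open water
LC_SNOW = "frac_snow_ice"
LC_TGB = "frac_deciduous_grassland"
LC_OTHER = "frac_other"
LANDCOVER_COLUMNS = (LC_SHRUB, LC_DISTURBED, LC_SNOW, LC_TGB, LC_OTHER)

MAR_RANGE_LABELS = ("R1", "R2", "R3")
MAR_R1_MAX = 630.0
MAR_R2_MAX = 1200.0
MAR_CAP = 2500.0


@dataclass(frozen=True)
class MaskLog:
    """Per-rule drop counts from one filtering pass."""

    n_input: int
    n_shrubland: int
    n_disturbed: int
    n_not_tgb: int
    n_mar_excluded: int
    n_kept: int


def _require_columns(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")


def apply_masks(
    table: pd.DataFrame,
    shrub_threshold: float = 0.5,
    disturbed_threshold: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Drop shrubland-dominated and human/water/snow-influenced cells.

    A cell is dropped when its shrubland fraction strictly exceeds
    ``shrub_threshold``, or when the combined human/water plus snow/ice
    fraction strictly exceeds ``disturbed_threshold``.
    """
    _require_columns(table, (LC_SHRUB, LC_DISTURBED, LC_SNOW))
    frac = table[[LC_SHRUB, LC_DISTURBED, LC_SNOW]].to_numpy(dtype=float)
    if np.any(~np.isfinite(frac)) or np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("land-cover fractions must be finite and in [0, 1]")
    drop = (frac[:, 0] > shrub_threshold) | (
        frac[:, 1] + frac[:, 2] > disturbed_threshold
    )
    return table.loc[~drop]


def identify_tgb(table: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """True where the deciduous-tree + grassland fraction strictly exceeds
    ``threshold`` (default 0.5): the tropical-grassy-biome flag."""
    _require_columns(table, (LC_TGB,))
    return table[LC_TGB] > threshold


def assign_mar_range(mar):
    """MAR-range label(s): R1 (≤630), R2 (630–1200), R3 (1200–2500),
    'excluded' above 2500 mm/y. Accepts a scalar or an array."""
    arr = np.asarray(mar, dtype=float)
    if np.any(arr < 0) or np.any(~np.isfinite(arr)):
        raise ValueError("MAR must be finite and non-negative")
    labels = np.where(
        arr <= MAR_R1_MAX,
        "R1",
        np.where(arr < MAR_R2_MAX, "R2", np.where(arr <= MAR_CAP, "R3", "excluded")),
    )
    return labels.item() if arr.ndim == 0 else labels


def build_analysis_table(
    table: pd.DataFrame,
    shrub_threshold: float = 0.5,
    disturbed_threshold: float = 1.0 / 3.0,
    tgb_threshold: float = 0.5,
) -> tuple[pd.DataFrame, MaskLog]:
    """Apply all filters and label MAR ranges.

    Returns the surviving rows (with a ``mar_range`` column added) and a
    log of how many cells each rule removed. Requires land-cover fraction
    columns and a ``MAR`` column.
    """
    _require_columns(table, (*LANDCOVER_COLUMNS[:4], "MAR"))
    n_input = len(table)
    shrub = table[LC_SHRUB] > shrub_threshold
    disturbed = (table[LC_DISTURBED] + table[LC_SNOW]) > disturbed_threshold
    masked = apply_masks(table, shrub_threshold, disturbed_threshold)
    tgb = masked[identify_tgb(masked, tgb_threshold)]
    labels = assign_mar_range(tgb["MAR"].to_numpy())
    kept = tgb[labels != "excluded"].copy()
    kept["mar_range"] = labels[labels != "excluded"]
    log = MaskLog(
        n_input=n_input,
        n_shrubland=int(shrub.sum()),
        n_disturbed=int((disturbed & ~shrub).sum()),
        n_not_tgb=len(masked) - len(tgb),
        n_mar_excluded=int((labels == "excluded").sum()),
        n_kept=len(kept),
    )
    return kept, log


def compare_medians(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between groups.

    Returns one row per group pair with the Mann–Whitney U statistic and
    two-sided p-value (exact for small tie-free samples, normal
    approximation otherwise).
    """
    for name, values in groups.items():
        if len(np.asarray(values)) < 2:
            raise ValueError(f"group {name!r} needs at least 2 values")
    rows = []
    for a, b in combinations(groups.keys(), 2):
        res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        rows.append(
            {"group_a": a, "group_b": b, "statistic": res.statistic, "pvalue": res.pvalue}
        )
    return pd.DataFrame(rows)
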