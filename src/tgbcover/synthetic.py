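"""Synthetic study generator.

Emulates the statistical structure of the satellite inputs so every
downstream stage is exercisable without downloads:

* daily rainfall per cell: inside a configurable set of wet months, rain
  falls on each day independently with probability ``event_prob`` (the
  target wet-season frequency lambda_w) and exponential depths with mean
  ``mean_depth`` (the target intensity alpha_w); dry-season days carry
  occasional light drizzle, which exercises the 0.1 mm/d wet-day threshold;
* burnt-area fractions whose derived fire intervals span several orders of
  magnitude, including unburnt cells;
* land-cover class fractions with cells that each filtering rule accepts
  and rejects;
* tree and grass cover drawn from binomial-logit generating models on the
  standardized predictors, with a binomial denominator of ``n_trials``
  (default 100, percent-cover resolution).

``make_dataset`` assembles a full synthetic study: cells are allocated to
the three mean-annual-rainfall ranges (defaults 694/783/215, the sizes of
the reference analysis), rainfall parameters are drawn per cell and the
realized series is redrawn until its MAR lands in the assigned range, so
the filtered analysis table reproduces the configured range counts
exactly. Additional distractor cells exercise the shrubland, human/water,
snow and MAR-cap filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._calendar import DAYS_PER_YEAR, day_mask, days_in_months, validate_months
from .fire import DEFAULT_EPSILON, fire_interval
from .filtering import (
    LANDCOVER_COLUMNS,
    LC_DISTURBED,
    LC_OTHER,
    LC_SHRUB,
    LC_SNOW,
    LC_TGB,
    assign_mar_range,
)
from .glm import DEFAULT_N_TRIALS, PREDICTORS, standardize, term_name
from .rainfall import DailyRainfallSeries, compute_metrics

__all__ = [
    "RainGenParams",
    "CoverGenParams",
    "Scenario",
    "SyntheticStudy",
    "DEFAULT_COVER_MODELS",
    "simulate_daily_rainfall",
    "simulate_burnt_area",
    "simulate_cover",
    "simulate_landcover",
    "draw_standardized_predictors",
    "make_dataset",
    "load_scenario",
]

#: Generating models: best-fit standardized-coefficient sets for tree (T)
#: and grass (G) cover in the low/intermediate/high rainfall ranges, used
#: as the default data-generating processes. Grass in R3, for which no
#: predictor carries signal, is generated from an intercept only.
DEFAULT_COVER_MODELS: dict[tuple[str, str], dict[str, float]] = {
    ("T", "R1"): {"intercept": -3.85, "MAR": 0.55},
    ("G", "R1"): {"intercept": 0.22, "SI": -0.42, "lambda_w": 0.38},
    ("T", "R2"): {"intercept": -1.48, "lambda_w": 0.49, "lambda_w^2": 0.14},
    ("G", "R2"): {"intercept": 0.73, "log_afi": -0.17, "lambda_w": -0.17},
    ("T", "R3"): {"intercept": -1.62, "alpha_w": -0.41},
    ("G", "R3"): {"intercept": -0.4},
}

#: Default cross-correlation of the five standardized predictors, loosely
#: matching the dry-range structure of the study region (rainfall frequency
#: strongly tied to MAR, intensity nearly independent of it).
DEFAULT_PREDICTOR_CORRELATION = np.array(
    [
        # MAR    SI    lam    alp    logAFI
        [1.00, -0.40, 0.73, 0.14, -0.35],
        [-0.40, 1.00, -0.55, 0.25, 0.25],
        [0.73, -0.55, 1.00, 0.00, -0.35],
        [0.14, 0.25, 0.00, 1.00, 0.00],
        [-0.35, 0.25, -0.35, 0.00, 1.00],
    ]
)


@dataclass(frozen=True)
class RainGenParams:
    """Parameters of the per-cell daily rainfall generator."""

    n_years: int
    wet_months: frozenset[int]
    event_prob: float  # per wet-season day; the target lambda_w (1/d)
    mean_depth: float  # exponential event depth mean; the target alpha_w (mm/d)
    dry_drizzle_prob: float = 0.05
    dry_mean_depth: float = 0.5  # mm/d
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "wet_months", validate_months(self.wet_months))
        if not 1 <= len(self.wet_months) <= 12:
            raise ValueError("wet_months must contain 1..12 months")
        if self.n_years < 1:
            raise ValueError("n_years must be at least 1")
        if not 0.0 <= self.event_prob <= 1.0:
            raise ValueError("event_prob must lie in [0, 1]")
        if self.event_prob > 0 and self.mean_depth <= 0.1:
            raise ValueError("mean_depth must exceed the 0.1 mm/d wet-day threshold")
        if not 0.0 <= self.dry_drizzle_prob <= 1.0:
            raise ValueError("dry_drizzle_prob must lie in [0, 1]")


@dataclass(frozen=True)
class CoverGenParams:
    """Parameters of the binomial cover generator."""

    coefficients: Mapping[str, float]  # term -> value, standardized scale
    n_trials: int = DEFAULT_N_TRIALS
    seed: int = 0

    def __post_init__(self):
        if "intercept" not in self.coefficients:
            raise ValueError("coefficients must include an 'intercept' term")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")


def _draw_depths(
    rng: np.random.Generator,
    wet_mask: np.ndarray,
    n_years: int,
    event_prob: float,
    mean_depth: float,
    dry_prob: float,
    dry_mean: float,
) -> np.ndarray:
    depths = np.zeros((n_years, DAYS_PER_YEAR))
    u = rng.random((n_years, DAYS_PER_YEAR))
    scale = np.where(wet_mask, mean_depth, dry_mean)
    prob = np.where(wet_mask, event_prob, dry_prob)
    raining = u < prob
    depths[raining] = rng.exponential(scale=np.broadcast_to(scale, depths.shape)[raining])
    return depths


def simulate_daily_rainfall(params: RainGenParams) -> DailyRainfallSeries:
    """Draw a multi-year daily rainfall series for one cell."""
    rng = np.random.default_rng(params.seed)
    wet_mask = day_mask(params.wet_months)
    depths = _draw_depths(
        rng,
        wet_mask,
        params.n_years,
        params.event_prob,
        params.mean_depth,
        params.dry_drizzle_prob,
        params.dry_mean_depth,
    )
    return DailyRainfallSeries(depths)


def simulate_burnt_area(
    n_cells: int,
    log_afi_range: tuple[float, float] = (0.0, 4.0),
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    zero_ba_fraction: float = 0.02,
) -> np.ndarray:
    """Per-cell mean annual burnt fractions spanning a fire-interval range.

    log10(AFI) is drawn uniformly on ``log_afi_range`` and inverted through
    the regularized definition, ``BA = 10**(-log_afi) - epsilon``. When the
    range top reaches the cap (``-log10(epsilon)``), a ``zero_ba_fraction``
    share of cells is pinned there, giving exactly unburnt cells (BA = 0).
    """
    lo, hi = float(log_afi_range[0]), float(log_afi_range[1])
    if not lo <= hi:
        raise ValueError("log_afi_range must be a non-empty interval")
    cap = -np.log10(epsilon)
    if lo < -0.1 - 1e-9 or hi > cap + 1e-9:
        raise ValueError(f"log_afi_range must lie within [-0.1, {cap:g}]")
    if n_cells == 0:
        return np.zeros(0)
    rng = np.random.default_rng(seed)
    u = rng.uniform(lo, hi, size=n_cells)
    if hi >= cap - 1e-9 and zero_ba_fraction > 0:
        n_zero = max(1, int(round(zero_ba_fraction * n_cells)))
        u[rng.choice(n_cells, size=min(n_zero, n_cells), replace=False)] = cap
    ba = 10.0 ** (-u) - epsilon
    ba[ba < 1e-15] = 0.0
    return ba


def simulate_cover(predictors: pd.DataFrame, params: CoverGenParams) -> np.ndarray:
    """Cover fractions from a binomial-logit generating model.

    Each term of ``params.coefficients`` (other than the intercept) names a
    column of ``predictors`` or the square of one (e.g. ``lambda_w^2``);
    the columns are expected to be standardized already. Returns
    ``Binomial(n_trials, logistic(eta)) / n_trials`` per row.
    """
    eta = np.full(len(predictors), float(params.coefficients["intercept"]))
    for term, value in params.coefficients.items():
        if term == "intercept":
            continue
        name, _, power = term.partition("^")
        if name not in predictors.columns:
            raise ValueError(f"unknown term {term!r}: no column {name!r}")
        x = predictors[name].to_numpy(dtype=float)
        eta += value * x ** (int(power) if power else 1)
    rng = np.random.default_rng(params.seed)
    return rng.binomial(params.n_trials, expit(eta)) / params.n_trials


_LANDCOVER_TYPES = (LC_TGB, LC_SHRUB, LC_DISTURBED, LC_SNOW, LC_OTHER)
_LANDCOVER_WEIGHTS = (0.78, 0.08, 0.08, 0.02, 0.04)


def _landcover_row(rng: np.random.Generator, dominant: str) -> dict[str, float]:
    dom = rng.uniform(0.55, 0.95)
    rest = 1.0 - dom
    if dominant == LC_TGB:
        # Biome cells must survive the masks: keep the combined human/water
        # + snow remainder below a third (rest <= 0.45, share <= 0.5 of it)
        # and shrubland below half.
        disturbed = rest * rng.uniform(0.0, 0.5)
        hw = disturbed * rng.uniform(0.0, 1.0)
        shrub_other = rest - disturbed
        shrub = shrub_other * rng.uniform(0.0, 1.0)
        parts = {
            LC_SHRUB: shrub,
            LC_DISTURBED: hw,
            LC_SNOW: disturbed - hw,
            LC_OTHER: shrub_other - shrub,
        }
    else:
        others = [c for c in LANDCOVER_COLUMNS if c != dominant]
        weights = rng.dirichlet(np.ones(len(others))) * rest
        parts = dict(zip(others, weights))
    row = {col: parts.get(col, dom) for col in LANDCOVER_COLUMNS}
    row[dominant] = dom
    return row


def simulate_landcover(n_cells: int, seed: int = 0) -> pd.DataFrame:
    """Per-cell land-cover class fractions (rows sum to 1).

    Cells are allocated deterministically across dominant types — mostly
    deciduous-tree/grassland (the biome of interest), with shrubland-,
    human/water-, snow- and other-dominated cells mixed in so each
    filtering rule has cells to accept and reject.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    counts = _largest_remainder(n_cells, _LANDCOVER_WEIGHTS)
    rng = np.random.default_rng(seed)
    rows = []
    for dominant, count in zip(_LANDCOVER_TYPES, counts):
        rows.extend(_landcover_row(rng, dominant) for _ in range(count))
    frame = pd.DataFrame(rows, columns=list(LANDCOVER_COLUMNS))
    if n_cells:
        frame = frame.iloc[rng.permutation(n_cells)].reset_index(drop=True)
    return frame


def _largest_remainder(n: int, weights: Sequence[float]) -> list[int]:
    quotas = np.asarray(weights, dtype=float) * n
    counts = np.floor(quotas).astype(int)
    order = np.argsort(-(quotas - counts))
    for i in range(n - counts.sum()):
        counts[order[i % len(weights)]] += 1
    return counts.tolist()


def draw_standardized_predictors(
    n: int,
    seed: int = 0,
    correlation: np.ndarray | None = None,
    columns: Sequence[str] = PREDICTORS,
) -> pd.DataFrame:
    """Multivariate-normal standardized predictors with a fixed
    cross-correlation (default :data:`DEFAULT_PREDICTOR_CORRELATION`)."""
    corr = DEFAULT_PREDICTOR_CORRELATION if correlation is None else np.asarray(correlation)
    if corr.shape != (len(columns), len(columns)):
        raise ValueError("correlation shape does not match columns")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, len(columns))) @ chol.T
    return pd.DataFrame(z, columns=list(columns))


# --------------------------------------------------------------------------
# Full-study scenario


@dataclass(frozen=True)
class Scenario:
    """Configuration of a full synthetic study.

    Per-range cell counts default to the reference analysis (694/783/215,
    1692 cells in total); per-range bounds on target MAR, wet-season month
    count, event probability and log10(AFI) shape the predictor marginals
    to plausible values for dry, mesic and humid grassy biomes.
    """

    n_cells: Mapping[str, int] = field(
        default_factory=lambda: {"R1": 694, "R2": 783, "R3": 215}
    )
    n_masked_cells: int = 60
    n_years: int = 11
    n_trials: int = DEFAULT_N_TRIALS
    seed: int = 0
    mar_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "R1": (150.0, 615.0),
            "R2": (650.0, 1190.0),
            "R3": (1230.0, 2450.0),
        }
    )
    wet_month_counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"R1": (4, 7), "R2": (5, 8), "R3": (6, 9)}
    )
    event_prob_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "R1": (0.15, 0.45),
            "R2": (0.35, 0.65),
            "R3": (0.45, 0.80),
        }
    )
    log_afi_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"R1": (0.3, 2.5), "R2": (0.0, 2.0), "R3": (0.7, 3.5)}
    )
    dry_drizzle_prob: float = 0.05
    dry_mean_depth: float = 0.5
    cover_models: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVER_MODELS)
    )
    p_thr: float = 0.5
    wet_day_threshold: float = 0.1
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        for label, n in self.n_cells.items():
            if label not in ("R1", "R2", "R3") or n < 0:
                raise ValueError(f"invalid cell count {label}={n}")
        if self.n_masked_cells < 0 or self.n_years < 1:
            raise ValueError("inconsistent scenario configuration")

    @property
    def n_total(self) -> int:
        return sum(self.n_cells.values()) + self.n_masked_cells


def load_scenario(path) -> Scenario:
    """Read a scenario from a flat YAML or TOML mapping of field values."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        raw = tomllib.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError("scenario file must contain a mapping")
    if "cover_models" in raw:
        raw["cover_models"] = {
            tuple(key.split("/")): value for key, value in raw["cover_models"].items()
        }
    for key in ("mar_bounds", "wet_month_counts", "event_prob_bounds", "log_afi_bounds"):
        if key in raw:
            raw[key] = {k: tuple(v) for k, v in raw[key].items()}
    return Scenario(**raw)


@dataclass(frozen=True)
class SyntheticStudy:
    """A generated study: raw per-cell inputs plus the derived analysis table."""

    scenario: Scenario
    daily: np.ndarray  # (n_cells, n_years, 365) rainfall depths, mm/d
    cells: pd.DataFrame  # per-cell raw inputs: coords, land cover, BA, T, G
    cell_table: pd.DataFrame  # derived analysis table (filtered cells only)
    standardize_params: dict[str, dict[str, tuple[float, float]]]  # per range
    gen_params: pd.DataFrame  # per-cell generating rainfall parameters

    @property
    def n_cells(self) -> int:
        return self.daily.shape[0]

    def series(self, index: int) -> DailyRainfallSeries:
        return DailyRainfallSeries(self.daily[index])


_MASKED_KINDS = (LC_SHRUB, LC_DISTURBED, LC_SNOW, "too_wet", LC_OTHER)
_MASKED_WEIGHTS = (0.35, 0.25, 0.05, 0.15, 0.20)

#: Fixed target-MAR margins used for rejection sampling of masked cells.
_TOO_WET_MAR = (2600.0, 3200.0)


def _draw_cell_rain(
    rng: np.random.Generator,
    scenario: Scenario,
    mar_lo: float,
    mar_hi: float,
    months_lo: int,
    months_hi: int,
    prob_lo: float,
    prob_hi: float,
    accept,
    max_attempts: int = 200,
):
    """Draw rainfall parameters and a realized series until ``accept(mar)``."""
    for _ in range(max_attempts):
        target_mar = rng.uniform(mar_lo, mar_hi)
        n_months = int(rng.integers(months_lo, months_hi + 1))
        start = int(rng.integers(1, 13))
        months = frozenset(((start - 1 + i) % 12) + 1 for i in range(n_months))
        event_prob = rng.uniform(prob_lo, prob_hi)
        l_w = days_in_months(months)
        drizzle = scenario.dry_drizzle_prob * scenario.dry_mean_depth * (365 - l_w)
        mean_depth = max(0.2, (target_mar - drizzle) / (event_prob * l_w))
        wet_mask = day_mask(months)
        depths = _draw_depths(
            rng,
            wet_mask,
            scenario.n_years,
            event_prob,
            mean_depth,
            scenario.dry_drizzle_prob,
            scenario.dry_mean_depth,
        )
        mar = depths.sum(axis=1).mean()
        if accept(mar):
            return depths, months, event_prob, mean_depth
    raise RuntimeError("rejection sampling failed to land in the target MAR range")


def make_dataset(scenario: Scenario | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate a full synthetic study.

    Cells are drawn range by range, redrawing any cell whose realized MAR
    falls outside its assigned range, so the filtered table reproduces the
    configured per-range counts exactly. Tree and grass cover are then
    drawn from the scenario's generating models evaluated on the
    within-range standardized predictors. ``seed`` overrides the
    scenario's seed.
    """
    scenario = scenario or Scenario()
    if seed is not None:
        scenario = replace(scenario, seed=int(seed))
    root = np.random.SeedSequence(scenario.seed)
    ss_cells, ss_cover, ss_landcover, ss_coords = root.spawn(4)

    n_total = scenario.n_total
    if n_total == 0:
        empty = pd.DataFrame(
            columns=["cell_id", "lon", "lat", *LANDCOVER_COLUMNS, "BA", "T", "G"]
        )
        empty_table = pd.DataFrame(
            columns=[
                "cell_id", "lon", "lat", "T", "G",
                "MAR", "SI", "lambda_w", "alpha_w", "log_afi", "mar_range",
            ]
        )
        return SyntheticStudy(
            scenario, np.zeros((0, scenario.n_years, DAYS_PER_YEAR)), empty,
            empty_table, {}, pd.DataFrame(),
        )

    cell_streams = ss_cells.spawn(n_total)
    lc_rng = np.random.default_rng(ss_landcover)
    coord_rng = np.random.default_rng(ss_coords)

    daily = np.zeros((n_total, scenario.n_years, DAYS_PER_YEAR))
    records = []
    gen_records = []
    idx = 0

    def _range_accept(label):
        return lambda mar: assign_mar_range(mar) == label

    for label in ("R1", "R2", "R3"):
        for _ in range(scenario.n_cells.get(label, 0)):
            rng = np.random.default_rng(cell_streams[idx])
            depths, months, event_prob, mean_depth = _draw_cell_rain(
                rng,
                scenario,
                *scenario.mar_bounds[label],
                *scenario.wet_month_counts[label],
                *scenario.event_prob_bounds[label],
                _range_accept(label),
            )
            daily[idx] = depths
            lo, hi = scenario.log_afi_bounds[label]
            log_afi = rng.uniform(lo, hi)
            ba = max(0.0, 10.0 ** (-log_afi) - scenario.epsilon)
            records.append(
                {"role": label, "BA": ba, **_landcover_row(lc_rng, LC_TGB)}
            )
            gen_records.append(
                {
                    "role": label,
                    "event_prob": event_prob,
                    "mean_depth": mean_depth,
                    "n_wet_months": len(months),
                }
            )
            idx += 1

    masked_counts = _largest_remainder(scenario.n_masked_cells, _MASKED_WEIGHTS)
    for kind, count in zip(_MASKED_KINDS, masked_counts):
        for _ in range(count):
            rng = np.random.default_rng(cell_streams[idx])
            if kind == "too_wet":
                depths, months, event_prob, mean_depth = _draw_cell_rain(
                    rng, scenario, *_TOO_WET_MAR, 9, 12, 0.55, 0.85,
                    lambda mar: mar > 2500.0,
                )
                lc = _landcover_row(lc_rng, LC_TGB)
            else:
                depths, months, event_prob, mean_depth = _draw_cell_rain(
                    rng, scenario, *scenario.mar_bounds["R2"],
                    *scenario.wet_month_counts["R2"],
                    *scenario.event_prob_bounds["R2"],
                    lambda mar: 630.0 < mar < 1200.0,
                )
                lc = _landcover_row(lc_rng, kind)
            daily[idx] = depths
            log_afi = rng.uniform(0.0, 3.0)
            records.append(
                {"role": f"masked:{kind}", "BA": max(0.0, 10.0 ** (-log_afi) - scenario.epsilon), **lc}
            )
            gen_records.append(
                {
                    "role": f"masked:{kind}",
                    "event_prob": event_prob,
                    "mean_depth": mean_depth,
                    "n_wet_months": len(months),
                }
            )
            idx += 1

    cells = pd.DataFrame(records)
    cells.insert(0, "cell_id", np.arange(n_total))
    cells.insert(1, "lon", np.round(-15.0 + 0.5 * (np.arange(n_total) % 90), 2))
    cells.insert(2, "lat", np.round(-35.0 + 0.5 * (np.arange(n_total) // 90), 2))
    del coord_rng  # grid coordinates are deterministic

    # Derived rainfall metrics for every cell.
    metrics = []
    for i in range(n_total):
        m = compute_metrics(
            DailyRainfallSeries(daily[i]),
            p_thr=scenario.p_thr,
            wet_day_threshold=scenario.wet_day_threshold,
        )
        metrics.append(
            {
                "MAR": m.mar, "SI": m.si, "lambda_w": m.lambda_w,
                "alpha_w": m.alpha_w, "MAR_w": m.mar_w, "L_w": m.l_w, "c": m.c,
            }
        )
    metrics = pd.DataFrame(metrics)
    fm = fire_interval(cells["BA"].to_numpy(), scenario.epsilon)
    metrics["log_afi"] = fm.log_afi

    # Cover for analysis cells: generating models on standardized
    # within-range predictors. Masked cells get nuisance draws.
    full = pd.concat([cells, metrics], axis=1)
    full["T"] = np.nan
    full["G"] = np.nan
    cover_rng = np.random.default_rng(ss_cover)
    std_params: dict[str, dict[str, tuple[float, float]]] = {}
    for label in ("R1", "R2", "R3"):
        rows = full.index[full["role"] == label]
        if len(rows) == 0:
            continue
        block = full.loc[rows, list(PREDICTORS)]
        block_std, params = standardize(block, PREDICTORS)
        std_params[label] = params
        for response in ("T", "G"):
            coeffs = scenario.cover_models[(response, label)]
            gen = CoverGenParams(
                coefficients=coeffs,
                n_trials=scenario.n_trials,
                seed=int(cover_rng.integers(2**31)),
            )
            full.loc[rows, response] = simulate_cover(block_std, gen)
    nuisance = full.index[full["T"].isna()]
    if len(nuisance):
        full.loc[nuisance, "T"] = cover_rng.binomial(
            scenario.n_trials, 0.3, size=len(nuisance)
        ) / scenario.n_trials
        full.loc[nuisance, "G"] = cover_rng.binomial(
            scenario.n_trials, 0.5, size=len(nuisance)
        ) / scenario.n_trials

    cells = full[
        ["cell_id", "lon", "lat", *LANDCOVER_COLUMNS, "BA", "T", "G", "role"]
    ].copy()
    analysis = full[full["role"].isin(("R1", "R2", "R3"))]
    cell_table = pd.DataFrame(
        {
            "cell_id": analysis["cell_id"],
            "lon": analysis["lon"],
            "lat": analysis["lat"],
            "T": analysis["T"],
            "G": analysis["G"],
            "MAR": analysis["MAR"],
            "SI": analysis["SI"],
            "lambda_w": analysis["lambda_w"],
            "alpha_w": analysis["alpha_w"],
            "log_afi": analysis["log_afi"],
            "mar_range": analysis["role"],
        }
    ).reset_index(drop=True)
    gen_params = pd.DataFrame(gen_records)
    gen_params.insert(0, "cell_id", np.arange(n_total))
    return SyntheticStudy(scenario, daily, cells, cell_table, std_params, gen_params)
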