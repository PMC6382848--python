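"""Average fire intervals from burnt-area fractions.

The average fire interval AFI (years) of a grid cell is the reciprocal of
its mean annual burnt-area fraction BA (1/y). A small regularising constant
``epsilon`` (default 1e-4/y) added to BA caps AFI at 10,000 y for unburnt
cells; the analysis works on log10(AFI) because AFI spans several orders of
magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FireMetrics", "fire_interval", "annual_burnt_fraction", "DEFAULT_EPSILON"]

DEFAULT_EPSILON = 1e-4  # 1/y; caps AFI at 10,000 y when BA = 0
AFI_CAP = 1.0 / DEFAULT_EPSILON


@dataclass(frozen=True)
class FireMetrics:
    ba: np.ndarray  # mean annual burnt fraction, 1/y
    afi: np.ndarray  # average fire interval, y
    log_afi: np.ndarray  # log10(AFI) = -log10(BA + epsilon)


def fire_interval(ba, epsilon: float = DEFAULT_EPSILON) -> FireMetrics:
    """AFI = 1/(BA + epsilon) and its decimal log; scalar or array BA."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    ba = np.asarray(ba, dtype=float)
    if np.any(ba < 0):
        raise ValueError("burnt-area fractions must be non-negative")
    afi = 1.0 / (ba + epsilon)
    return FireMetrics(ba=ba, afi=afi, log_afi=np.log10(afi))


def annual_burnt_fraction(monthly) -> np.ndarray | float:
    """Mean annual burnt fraction from monthly burnt-area fractions.

    ``monthly`` has months on the last axis and years on the second-to-last
    (shape ``(..., n_years, 12)``); a yearly fraction is the month sum
    clipped at 1 (area re-burnt within a year is counted once), and BA is
    the mean over years.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.ndim < 2:
        raise ValueError("monthly must have shape (..., n_years, n_months)")
    if np.any(monthly < 0) or np.any(monthly > 1):
        raise ValueError("monthly burnt fractions must lie in [0, 1]")
    yearly = np.minimum(monthly.sum(axis=-1), 1.0)
    ba = yearly.mean(axis=-1)
    return float(ba) if ba.ndim == 0 else ba
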