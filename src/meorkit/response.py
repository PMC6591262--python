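"""Biomass-dose vs oil-recovery regression.

Oil produced from treated columns (% of residual oil in place) rises
linearly with the optical density (OD600) of the injected biomass, with a
steeper slope when nitrate is co-injected:

    %ROIP = m * OD600 + b

Two derived comparisons quantify the nitrate effect: the fold-change in
predicted recovery at a given OD600, and the ratio of biomass doses needed
to hit a target recovery without vs with nitrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BiomassDose",
    "RegressionFit",
    "fit_ols",
    "predict_roip",
    "nitrate_fold_change",
    "equivalent_biomass_ratio",
]

#: Fits with fewer points than this are flagged small-sample.
SMALL_SAMPLE_N = 8


@dataclass(frozen=True)
class BiomassDose:
    od600: float
    percent_roip: float
    nitrate_present: bool = False

    def __post_init__(self) -> None:
        if self.od600 < 0 or self.percent_roip < 0:
            raise ValueError("od600 and percent_roip must be non-negative")


@dataclass(frozen=True)
class RegressionFit:
    slope: float  # %ROIP per OD600 unit
    intercept: float  # %ROIP
    r2: float
    n: int
    small_sample: bool = False

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a fit needs at least two points")
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError("r2 must lie in [0, 1]")


def fit_ols(points: Sequence[BiomassDose]) -> RegressionFit:
    """Ordinary least squares of %ROIP on OD600 for one nitrate condition.

    r2 is the squared Pearson correlation, identical to OLS R^2 with
    intercept.  Fits on fewer than 8 points carry a small-sample flag.
    """
    if len(points) < 2:
        raise ValueError("need at least two points")
    x = np.array([p.od600 for p in points], dtype=float)
    y = np.array([p.percent_roip for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all OD600 values identical")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        n=len(points),
        small_sample=len(points) < SMALL_SAMPLE_N,
    )


def predict_roip(fit: RegressionFit, od600: float) -> float:
    """Predicted %ROIP at a biomass dose."""
    if od600 < 0:
        raise ValueError("od600 must be non-negative")
    return fit.slope * od600 + fit.intercept


def nitrate_fold_change(
    fit_no_nitrate: RegressionFit, fit_nitrate: RegressionFit, od600: float
) -> float:
    """Predicted recovery with nitrate over without, at the same biomass dose."""
    denom = predict_roip(fit_no_nitrate, od600)
    num = predict_roip(fit_nitrate, od600)
    if denom <= 0:
        raise ValueError("no-nitrate prediction is non-positive")
    return num / denom


def equivalent_biomass_ratio(
    fit_no_nitrate: RegressionFit, fit_nitrate: RegressionFit, target_percent_roip: float
) -> float:
    """Biomass-dose ratio (without / with nitrate) reaching the same recovery.

    Inverts both lines at the target: [(y-b0)/m0] / [(y-bN)/mN].  The target
    must exceed both intercepts.
    """
    if (
        target_percent_roip <= fit_no_nitrate.intercept
        or target_percent_roip <= fit_nitrate.intercept
    ):
        raise ValueError("target recovery at or below an intercept is unreachable")
    od_without = (target_percent_roip - fit_no_nitrate.intercept) / fit_no_nitrate.slope
    od_with = (target_percent_roip - fit_nitrate.intercept) / fit_nitrate.slope
    return od_without / od_with
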