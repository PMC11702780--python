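"""Relative protein expression from gel densitometry dilution series.

For each sample a dilution series (a range of loading volumes run on the
same gel) gives optical density (OD) as a function of loading volume for the
protein of interest and for myosin heavy chain (MHC).  Within the linear
range of the stain, OD is proportional to the loaded amount, so the OLS
slope of OD on volume measures concentration while cancelling lane-to-lane
loading differences.  Expression is then reported as the target/MHC slope
ratio, and finally as a percentage of the mean ratio of the wild-type
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class DilutionSeries:
    sample_id: str
    protein: str  # e.g. nebulin, titin, MHC
    loading_volumes: np.ndarray  # uL, strictly increasing
    od_values: np.ndarray  # AU

    def __post_init__(self) -> None:
        self.loading_volumes = np.asarray(self.loading_volumes, dtype=float)
        self.od_values = np.asarray(self.od_values, dtype=float)
        if self.loading_volumes.shape != self.od_values.shape:
            raise ValueError("volumes and ODs differ in length")
        if np.any(self.loading_volumes <= 0) or np.any(np.diff(self.loading_volumes) <= 0):
            raise ValueError("loading volumes must be positive and strictly increasing")
        if np.any(self.od_values < 0):
            raise ValueError("OD values must be non-negative")


@dataclass
class SlopeFit:
    slope: float  # AU/uL
    intercept: float
    r_squared: float
    n: int


def fit_od_slope(series: DilutionSeries, through_origin: bool = False) -> SlopeFit:
    """OLS slope of OD on loading volume.

    The intercept is estimated by default (background staining gives a
    nonzero OD at zero load); ``through_origin=True`` forces it to zero.
    An R^2 below 0.9 triggers a warning — usually saturation of the stain
    at the highest loads.
    """
    x, y = series.loading_volumes, series.od_values
    if x.size < 3:
        raise ValueError("need at least 3 points for a slope fit")
    if through_origin:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        ss_res = float(np.sum((y - slope * x) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    if np.all(y == y[0]):
        r2 = 1.0  # a perfectly flat series is perfectly fit by slope 0
        warnings.warn(
            f"{series.sample_id}/{series.protein}: OD constant, slope 0", stacklevel=2
        )
    elif r2 < 0.9:
        warnings.warn(
            f"{series.sample_id}/{series.protein}: R^2 = {r2:.3f} < 0.9 "
            "(possible saturation or nonlinearity)",
            stacklevel=2,
        )
    return SlopeFit(slope=slope, intercept=intercept, r_squared=r2, n=int(x.size))


def expression_ratio(target_slope: float, mhc_slope: float) -> float:
    """Target protein slope normalized to the MHC slope of the same sample."""
    if mhc_slope <= 0:
        raise ValueError("MHC slope must be positive")
    return target_slope / mhc_slope


def percent_of_wt(ratios: dict[str, float], wt_sample_ids: list[str]) -> dict[str, float]:
    """Express per-sample ratios as percent of the wild-type mean ratio."""
    if not wt_sample_ids:
        raise ValueError("need at least one WT sample")
    missing = [s for s in wt_sample_ids if s not in ratios]
    if missing:
        raise ValueError(f"WT samples missing from ratios: {missing}")
    wt_mean = float(np.mean([ratios[s] for s in wt_sample_ids]))
    if wt_mean == 0:
        raise ValueError("WT mean ratio is zero")
    return {s: 100.0 * r / wt_mean for s, r in ratios.items()}
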