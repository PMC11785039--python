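"""Xenograft growth kinetics: caliper volumes, exponential rates, endpoint
fold-increases, and the 2-way interaction ANOVA quantifying chemo-sensitization.

Volume follows the ellipsoid approximation V = L*W*H*pi/6 (mm^3).  Each
tumor's growth rate k (per day) is the slope of the least-squares line of
ln(V) on day, i.e. exponential kinetics V(t) = V0 * exp(k*t).  Whether a
genetic perturbation (the ``vector`` factor) sensitizes tumors to a drug is
tested as the vector x treatment interaction of a two-way ANOVA on a per-tumor
endpoint (fold-increase or growth rate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import EmptyCellError, MeasurementError
from .io import TumorSeries

logger = logging.getLogger(__name__)

__all__ = ["GrowthFit", "tumor_volume", "growth_rate", "fit_growth", "interaction_anova"]


@dataclass(frozen=True)
class GrowthFit:
    tumor_id: str
    vector: str
    treatment: str
    rate_k: float  # per-day exponential rate
    v0: float  # fitted day-0 volume, mm^3
    fold_increase: float  # last / first recorded volume


def tumor_volume(L: float, W: float, H: float) -> float:
    """Ellipsoid volume estimate from three caliper dimensions (mm -> mm^3)."""
    if L < 0 or W < 0 or H < 0:
        raise MeasurementError(f"negative dimension in ({L}, {W}, {H})")
    return L * W * H * math.pi / 6.0


def growth_rate(series: TumorSeries, day_min: float | None = None, day_max: float | None = None) -> GrowthFit:
    """Fit exponential kinetics to one tumor's volume series.

    Zero-volume timepoints are excluded from the log-linear fit (with a logged
    count); ``day_min``/``day_max`` optionally restrict the fitting window.
    The fold-increase endpoint uses the first and last recorded measurements
    regardless of the window.
    """
    days = np.asarray(series.days, dtype=float)
    volumes = series.volumes()
    if volumes.size < 2:
        raise MeasurementError(f"tumor {series.tumor_id!r}: need >=2 timepoints")
    if volumes[0] <= 0:
        raise MeasurementError(f"tumor {series.tumor_id!r}: zero baseline volume")
    fold_increase = float(volumes[-1] / volumes[0])
    mask = volumes > 0
    if day_min is not None:
        mask &= days >= day_min
    if day_max is not None:
        mask &= days <= day_max
    n_dropped = int((~(volumes > 0)).sum())
    if n_dropped:
        logger.info("tumor %s: excluded %d zero-volume timepoint(s)", series.tumor_id, n_dropped)
    if mask.sum() < 2:
        raise MeasurementError(
            f"tumor {series.tumor_id!r}: fewer than 2 positive-volume points in window"
        )
    slope, intercept = np.polyfit(days[mask], np.log(volumes[mask]), 1)
    return GrowthFit(
        tumor_id=series.tumor_id,
        vector=series.vector,
        treatment=series.treatment,
        rate_k=float(slope),
        v0=float(np.exp(intercept)),
        fold_increase=fold_increase,
    )


def fit_growth(series: Sequence[TumorSeries], **window) -> list[GrowthFit]:
    """Per-tumor exponential fits for a whole experiment."""
    return [growth_rate(s, **window) for s in series]


def interaction_anova(
    endpoints: Sequence[float],
    vector: Sequence[str],
    treatment: Sequence[str],
) -> tuple[float, float, pd.DataFrame]:
    """Two-way ANOVA interaction test on per-tumor endpoints.

    Returns (F, p) for the vector x treatment interaction plus the 2x2 table
    of cell means.  Type II sums of squares are used, which coincide with
    Type I/III for the interaction term on balanced data.
    """
    df = pd.DataFrame(
        {
            "endpoint": np.asarray(endpoints, dtype=float),
            "vector": [str(v) for v in vector],
            "treatment": [str(t) for t in treatment],
        }
    )
    counts = df.groupby(["vector", "treatment"]).size()
    if len(counts) != 4 or (counts < 2).any():
        raise EmptyCellError(
            f"2-way ANOVA needs >=2 tumors in each of 4 cells, got {counts.to_dict()}"
        )
    model = smf.ols("endpoint ~ C(vector) * C(treatment)", data=df).fit()
    if model.ssr <= 1e-24 * max(1.0, float(np.var(df["endpoint"]))):
        # saturated/noise-free data: interaction SS determines the call directly
        anova = sm.stats.anova_lm(model, typ=2)
        ss_int = float(anova.loc["C(vector):C(treatment)", "sum_sq"])
        return (0.0, 1.0, _cell_means(df)) if ss_int <= 1e-18 else (float("inf"), 0.0, _cell_means(df))
    anova = sm.stats.anova_lm(model, typ=2)
    row = anova.loc["C(vector):C(treatment)"]
    return float(row["F"]), float(row["PR(>F)"]), _cell_means(df)


def _cell_means(df: pd.DataFrame) -> pd.DataFrame:
    return df.groupby(["vector", "treatment"])["endpoint"].mean().unstack()
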