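"""Genetic-gain trend estimation from breeding values.

The rate of genetic gain of a breeding program is estimated by ordinary
least squares of line breeding values on either the year the originating
cross was made (gain per year) or the line's equivalent complete
generations (gain per breeding cycle).  Gains are reported in trait units
per predictor unit and, for context, as a percentage of the fitted value at
the first predictor value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger("ricegain")

PREDICTORS = ("cross_year", "eqg")


@dataclass
class TrendEstimate:
    predictor: str
    slope: float
    slope_se: float
    intercept: float
    percent_per_unit: float
    n_lines: int
    n_excluded: int  # lines missing the predictor

    @property
    def baseline(self) -> float:
        """Fitted value at the first (smallest) predictor value."""
        return self.intercept


def regress_trend(
    bvs: pd.DataFrame,
    predictor: str = "cross_year",
    value_col: str = "bv_yield",
    subset: Optional[pd.Series] = None,
    weight_by_reliability: bool = False,
    cluster_se: bool = False,
) -> TrendEstimate:
    """OLS of breeding value on ``cross_year`` or ``eqg``.

    ``subset`` is an optional boolean mask (e.g. released varieties only).
    Lines missing the predictor are excluded and counted.  A
    reliability-weighted (WLS) variant is available but not the default.
    The percentage rate is slope / fitted value at the first predictor
    value x 100.

    ``cluster_se=True`` reports a cluster-robust slope standard error with
    clusters at distinct predictor values: breeding values of lines from
    the same cohort share parents and environments, so the iid OLS standard
    error understates the trend's sampling uncertainty.  The point estimate
    is unchanged.
    """
    if predictor not in PREDICTORS:
        raise ValueError(f"predictor must be one of {PREDICTORS}")
    df = bvs if subset is None else bvs.loc[np.asarray(subset, dtype=bool)]
    ok = df[predictor].notna() & df[value_col].notna()
    n_excluded = int((~ok).sum())
    df = df.loc[ok]
    if len(df) < 3:
        raise ValueError(f"need at least 3 lines with {predictor}; got {len(df)}")
    x = df[predictor].astype(float).to_numpy()
    y = df[value_col].astype(float).to_numpy()
    if np.ptp(x) == 0:
        raise ValueError(f"all {predictor} values identical; no trend estimable")
    X = sm.add_constant(x)
    if weight_by_reliability:
        w = df["reliability"].astype(float).clip(lower=1e-6).to_numpy()
        model = sm.WLS(y, X, weights=w)
    else:
        model = sm.OLS(y, X)
    if cluster_se:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": x})
    else:
        res = model.fit()
    intercept, slope = res.params
    se = res.bse[1]
    fitted_first = intercept + slope * x.min()
    pct = slope / fitted_first * 100.0 if fitted_first != 0 else np.nan
    logger.info(
        "trend on %s: slope=%.4g (se %.3g), %.3g%% per unit, n=%d (excluded %d)",
        predictor, slope, se, pct, len(df), n_excluded,
    )
    return TrendEstimate(
        predictor=predictor,
        slope=float(slope),
        slope_se=float(se),
        intercept=float(intercept),
        percent_per_unit=float(pct),
        n_lines=len(df),
        n_excluded=n_excluded,
    )


def yearly_summary(bvs: pd.DataFrame, value_col: str = "bv_yield") -> pd.DataFrame:
    """Per-cross-year means of breeding value with SE, n, reliability, EqG.

    SE = sd / sqrt(n); years with a single line carry a missing SE; years
    with no lines are absent from the output.
    """
    df = bvs.loc[bvs["cross_year"].notna() & bvs[value_col].notna()].copy()
    df["cross_year"] = df["cross_year"].astype(int)
    g = df.groupby("cross_year")
    out = pd.DataFrame(
        {
            "mean_bv": g[value_col].mean(),
            "se_bv": g[value_col].std(ddof=1) / np.sqrt(g[value_col].count()),
            "n": g[value_col].count(),
            "mean_reliability": g["reliability"].mean()
            if "reliability" in df.columns
            else np.nan,
            "mean_eqg": g["eqg"].mean() if "eqg" in df.columns else np.nan,
        }
    ).reset_index()
    out.loc[out["n"] == 1, "se_bv"] = np.nan
    return out
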