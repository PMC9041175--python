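"""Analytical calibration statistics.

Ordinary least squares of response on concentration, coefficient of
determination, detection limits from the intercept's standard error

    LOD = 3.3 * se(intercept) / slope
    LOQ = 10  * se(intercept) / slope

inverse prediction, relative standard deviations and inter-/intra-day
precision tables, plus a leave-one-extreme-out linear-range check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CalibrationSeries",
    "CalibrationFit",
    "PrecisionReport",
    "fit_calibration",
    "rsd",
    "precision_table",
    "predict_concentration",
    "linear_range_check",
]

LOD_FACTOR = 3.3
LOQ_FACTOR = 10.0


@dataclass(frozen=True)
class CalibrationSeries:
    """A concentration-response series with optional day/replicate labels."""

    concentration: np.ndarray
    response: np.ndarray
    unit: str = ""
    day: np.ndarray | None = None
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if c.shape != r.shape or c.ndim != 1:
            raise ValueError("concentration and response must be matching 1-D arrays")
        if not np.all(np.isfinite(r)) or not np.all(np.isfinite(c)):
            raise ValueError("series values must be finite")
        object.__setattr__(self, "concentration", c)
        object.__setattr__(self, "response", r)
        for name in ("day", "replicate"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != c.shape:
                    raise ValueError(f"{name} labels must match the series length")
                object.__setattr__(self, name, v)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: str = "") -> "CalibrationSeries":
        return cls(
            concentration=df["concentration"].to_numpy(dtype=float),
            response=df["response"].to_numpy(dtype=float),
            unit=unit or df.attrs.get("unit", ""),
            day=df["day"].to_numpy() if "day" in df else None,
            replicate=df["replicate"].to_numpy() if "replicate" in df else None,
        )

    @property
    def n_levels(self) -> int:
        return int(np.unique(self.concentration).size)

    def __len__(self) -> int:
        return int(self.concentration.size)


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    r2: float
    lod: float | None
    loq: float | None
    n: int
    dof: int
    residual_sd: float
    unit: str = ""
    lod_applicable: bool = True

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "se_slope": self.se_slope,
            "se_intercept": self.se_intercept,
            "r2": self.r2,
            "lod": self.lod,
            "loq": self.loq,
            "n": self.n,
            "dof": self.dof,
            "residual_sd": self.residual_sd,
            "unit": self.unit,
            "lod_applicable": self.lod_applicable,
        }

    def report_rounded(self) -> dict:
        """Values at reporting precision: R2 to 3 decimals, LOD/LOQ to 1."""
        return {
            "r2": round(self.r2, 3),
            "lod": None if self.lod is None else round(self.lod, 1),
            "loq": None if self.loq is None else round(self.loq, 1),
        }


def fit_calibration(series: CalibrationSeries) -> CalibrationFit:
    """Unweighted OLS of response on concentration with LOD/LOQ.

    Requires >= 3 distinct concentration levels.  A nonpositive slope still
    returns the fit but flags LOD/LOQ as not applicable.
    """
    if series.n_levels < 3:
        raise ValueError(
            f"need >= 3 distinct concentration levels, got {series.n_levels}"
        )
    x = series.concentration
    if np.var(x) == 0:
        raise ValueError("degenerate design: zero concentration variance")
    model = sm.OLS(series.response, sm.add_constant(x)).fit()
    intercept, slope = model.params
    se_intercept, se_slope = model.bse
    s = math.sqrt(model.mse_resid)
    applicable = bool(slope > 0)
    lod = LOD_FACTOR * se_intercept / slope if applicable else None
    loq = LOQ_FACTOR * se_intercept / slope if applicable else None
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        se_slope=float(se_slope),
        se_intercept=float(se_intercept),
        r2=float(model.rsquared),
        lod=lod,
        loq=loq,
        n=len(series),
        dof=int(model.df_resid),
        residual_sd=s,
        unit=series.unit,
        lod_applicable=applicable,
    )


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, 100 * sd(n-1) / mean, in percent.

    NaN (flagged undefined) when the mean is zero.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("rsd requires at least 2 values")
    mean = v.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / mean)


@dataclass(frozen=True)
class PrecisionReport:
    """Per-level inter-/intra-day RSDs with column averages."""

    table: pd.DataFrame  # index: concentration; columns: mean_response, inter_day_rsd, intra_day_rsd
    inter_day_average: float
    intra_day_average: float
    n_days: int
    n_replicates: int
    excluded_levels: tuple[float, ...] = ()

    def to_dict(self) -> dict:
        return {
            "levels": self.table.reset_index().to_dict(orient="records"),
            "inter_day_average_rsd": self.inter_day_average,
            "intra_day_average_rsd": self.intra_day_average,
            "n_days": self.n_days,
            "n_replicates": self.n_replicates,
            "excluded_levels": list(self.excluded_levels),
        }


def precision_table(series: CalibrationSeries) -> PrecisionReport:
    """Inter-day RSD (over day means) and intra-day RSD (over within-day
    replicates, averaged across days) per concentration level.

    Levels with a single replicate per day and a single day carry no
    precision information and are excluded from the column averages.
    """
    if series.day is None or series.replicate is None:
        raise ValueError("precision_table requires day and replicate labels")
    df = pd.DataFrame(
        {
            "concentration": series.concentration,
            "response": series.response,
            "day": series.day,
            "replicate": series.replicate,
        }
    )
    rows = []
    excluded = []
    for conc, grp in df.groupby("concentration", sort=True):
        day_means = grp.groupby("day")["response"].mean()
        inter = rsd(day_means.to_numpy()) if day_means.size >= 2 else float("nan")
        intra_vals = [
            rsd(g["response"].to_numpy())
            for _, g in grp.groupby("day")
            if len(g) >= 2
        ]
        intra = float(np.mean(intra_vals)) if intra_vals else float("nan")
        if math.isnan(inter) and math.isnan(intra):
            excluded.append(float(conc))
        rows.append(
            {
                "concentration": float(conc),
                "mean_response": float(grp["response"].mean()),
                "inter_day_rsd": inter,
                "intra_day_rsd": intra,
            }
        )
    table = pd.DataFrame(rows).set_index("concentration")
    return PrecisionReport(
        table=table,
        inter_day_average=float(np.nanmean(table["inter_day_rsd"]))
        if table["inter_day_rsd"].notna().any()
        else float("nan"),
        intra_day_average=float(np.nanmean(table["intra_day_rsd"]))
        if table["intra_day_rsd"].notna().any()
        else float("nan"),
        n_days=int(pd.unique(df["day"]).size),
        n_replicates=int(df.groupby(["concentration", "day"]).size().max()),
        excluded_levels=tuple(excluded),
    )


def predict_concentration(fit: CalibrationFit, absorbance: float) -> tuple[float, str]:
    """Inverse prediction (A - a)/b with a below-LOD/LOQ annotation.

    Returns ``(concentration, flag)`` with flag one of ``ok``, ``below_loq``,
    ``below_lod``.
    """
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope calibration")
    conc = (absorbance - fit.intercept) / fit.slope
    flag = "ok"
    if fit.lod is not None and conc < fit.lod:
        flag = "below_lod"
    elif fit.loq is not None and conc < fit.loq:
        flag = "below_loq"
    return float(conc), flag


@dataclass(frozen=True)
class LinearRangeReport:
    flagged_level: float | None
    studentized_residual: float
    threshold: float
    reduced_fit: CalibrationFit


def linear_range_check(
    series: CalibrationSeries, threshold: float = 3.0
) -> LinearRangeReport:
    """Leave-one-extreme-out divergence check on the top concentration level.

    Refits without the highest level and flags it when the studentized
    prediction residual of its mean response exceeds ``threshold``.
    """
    if series.n_levels < 4:
        raise ValueError("linear_range_check requires >= 4 levels")
    top = series.concentration.max()
    keep = series.concentration < top
    reduced = CalibrationSeries(
        concentration=series.concentration[keep],
        response=series.response[keep],
        unit=series.unit,
    )
    fit = fit_calibration(reduced)
    x = reduced.concentration
    n = len(reduced)
    sxx = float(((x - x.mean()) ** 2).sum())
    y_top = float(series.response[~keep].mean())
    pred = fit.intercept + fit.slope * top
    # prediction standard error for a new observation at x = top
    se_pred = fit.residual_sd * math.sqrt(1.0 + 1.0 / n + (top - x.mean()) ** 2 / sxx)
    t = (y_top - pred) / se_pred
    return LinearRangeReport(
        flagged_level=float(top) if abs(t) > threshold else None,
        studentized_residual=float(t),
        threshold=threshold,
        reduced_fit=fit,
    )
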