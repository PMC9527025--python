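"""Time-vs-distance calibration and divergence-time prediction.

Under a strict molecular clock the expected genetic distance between two
lineages grows linearly with the time since their divergence (until multiple
hits saturate the signal).  Given published node ages y (My) for species
pairs with measured percent distances x, a least-squares line

    y = a·x + b        (unconstrained), or
    y = a·x            (constrained through the origin)

calibrates distance against time; the distance of a newly discovered taxon
to its nearest relative is then inserted into the line to estimate a
*minimum* divergence time.  R² is the centred 1 − SSres/SStot for the
unconstrained fit and the uncentred 1 − SSres/Σy² for the through-origin
fit (the centred form is misleading when no intercept is estimated).

Uncertainty on a prediction is reported either as an ordinary regression
prediction interval, or as a user-supplied fixed half-width matching the
convention of reading error bars off the source chronogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chronogram import PairTimes
from .msa import PairRangeTable

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationTable",
    "CalibrationFit",
    "Prediction",
    "CalibrationError",
    "build_calibration_table",
    "fit_calibration",
    "predict_time",
    "distance_range_summary",
    "MODES",
]

MODES = ("unconstrained", "through_origin")


class CalibrationError(ValueError):
    """Raised for degenerate or malformed calibration inputs."""


@dataclass(frozen=True)
class CalibrationTable:
    """Species pairs with percent distance x and divergence time y (My)."""

    df: pd.DataFrame  # columns: species_a, species_b, distance_percent, time_my

    COLUMNS = ("species_a", "species_b", "distance_percent", "time_my")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.df.columns:
                raise CalibrationError(f"calibration table missing column {col!r}")
        if (self.df["distance_percent"] < 0).any():
            raise CalibrationError("negative distance in calibration table")
        if (self.df["time_my"] <= 0).any():
            raise CalibrationError("non-positive divergence time in calibration table")
        keys = {
            tuple(sorted((a, b)))
            for a, b in zip(self.df["species_a"], self.df["species_b"])
        }
        if len(keys) != len(self.df):
            raise CalibrationError("duplicate species pair in calibration table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df["distance_percent"].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["time_my"].to_numpy(dtype=float)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, float, float]]
    ) -> "CalibrationTable":
        return cls(pd.DataFrame(records, columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CalibrationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


def build_calibration_table(
    ranges: PairRangeTable,
    times: PairTimes,
    *,
    summary: str = "mean",
    exclude: Sequence[str] = (),
) -> CalibrationTable:
    """Join a percent-range table with a pair-time table.

    ``summary`` picks the x value from each pair's (min, max) percent range:
    ``"mean"`` (midpoint, default), ``"min"`` or ``"max"``.  Pairs present
    in only one of the two tables are dropped with a logged count; pairs
    involving a species in ``exclude`` are omitted (used to keep a focal
    taxon out of its own calibration).  At least two shared pairs are
    required.
    """
    if summary not in ("mean", "min", "max"):
        raise CalibrationError(f"unknown range summary {summary!r}")
    excluded = set(exclude)
    records = []
    dropped = 0
    for (a, b), (lo, hi) in sorted(ranges.between.items()):
        if a in excluded or b in excluded:
            continue
        if (a, b) not in times:
            dropped += 1
            continue
        x = {"mean": (lo + hi) / 2.0, "min": lo, "max": hi}[summary]
        records.append((a, b, x, times.get(a, b)))
    n_time_only = sum(
        1
        for (a, b) in times.times
        if a not in excluded
        and b not in excluded
        and (a, b) not in {tuple(sorted(p)) for p in ranges.between}
    )
    dropped += n_time_only
    if dropped:
        logger.info(
            "build_calibration_table: dropped %d pairs present in only one table",
            dropped,
        )
    if len(records) < 2:
        raise CalibrationError(
            f"only {len(records)} species pairs shared between the distance "
            "and time tables; need at least 2"
        )
    return CalibrationTable.from_records(records)


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted calibration line.

    ``slope`` is in My per percent distance; ``intercept`` is 0 in
    ``through_origin`` mode.  The fitted x/y data are retained (when the fit
    came from data) so prediction intervals can be computed later; fits may
    also be constructed directly from published coefficients, in which case
    only fixed-width or point predictions are available.
    """

    mode: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    x: np.ndarray | None = field(default=None, repr=False, compare=False)
    y: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise CalibrationError(f"unknown fit mode {self.mode!r}")

    def predict_point(self, x: float) -> float:
        return self.slope * float(x) + self.intercept

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def fit_calibration(
    table: CalibrationTable, mode: str = "unconstrained"
) -> CalibrationFit:
    """Least-squares calibration fit in the requested mode.

    Unconstrained: closed-form OLS slope/intercept with centred
    R² = 1 − SSres/SStot.  Through-origin: slope = Σxy/Σx² with uncentred
    R² = 1 − SSres/Σy².  Degenerate designs (all x identical, or all x zero
    through the origin) are rejected.
    """
    x, y = table.x, table.y
    n = len(x)
    if mode == "unconstrained":
        if n < 2:
            raise CalibrationError("unconstrained fit needs at least 2 points")
        x_mean, y_mean = x.mean(), y.mean()
        sxx = float(((x - x_mean) ** 2).sum())
        if sxx == 0.0:
            raise CalibrationError("all x values identical; slope undefined")
        slope = float(((x - x_mean) * (y - y_mean)).sum()) / sxx
        intercept = float(y_mean - slope * x_mean)
        resid = y - (slope * x + intercept)
        ss_res = float((resid**2).sum())
        ss_tot = float(((y - y_mean) ** 2).sum())
        r2 = 1.0 if ss_tot == 0.0 and ss_res < 1e-300 else (
            0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
        )
    elif mode == "through_origin":
        if n < 1:
            raise CalibrationError("through-origin fit needs at least 1 point")
        sx2 = float((x**2).sum())
        if sx2 == 0.0:
            raise CalibrationError("all x values zero; slope undefined")
        slope = float((x * y).sum()) / sx2
        intercept = 0.0
        resid = y - slope * x
        ss_res = float((resid**2).sum())
        sy2 = float((y**2).sum())
        r2 = 1.0 if sy2 == 0.0 else 1.0 - ss_res / sy2
    else:
        raise CalibrationError(f"unknown fit mode {mode!r}")
    return CalibrationFit(
        mode=mode,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=n,
        x=x.copy(),
        y=y.copy(),
    )


@dataclass(frozen=True)
class Prediction:
    """A predicted divergence time with an uncertainty interval."""

    x_input: float
    point: float
    lower: float
    upper: float
    #: how the interval was obtained, e.g. "prediction_interval_95" or
    #: "fixed_halfwidth_4.0"
    method: str
    #: True when a negative lower bound (or point) was clipped to 0
    clipped: bool = False

    def to_dict(self) -> dict:
        return {
            "x_percent": self.x_input,
            "point_my": self.point,
            "lower_my": self.lower,
            "upper_my": self.upper,
            "interval_method": self.method,
            "clipped": self.clipped,
        }


def predict_time(
    fit: CalibrationFit,
    x: float,
    *,
    interval: str = "prediction",
    level: float = 0.95,
    fixed_halfwidth: float | None = None,
) -> Prediction:
    """Insert a percent distance into the calibration line.

    ``interval`` is ``"prediction"`` (regression prediction interval at
    ``level``, requiring the fit's data and at least 3 points) or ``"none"``.
    A ``fixed_halfwidth`` (My) overrides both, mirroring the convention of
    quoting a half-width read off the source study's uncertainty bars.
    Negative bounds are clipped to zero and flagged.
    """
    if x < 0:
        raise CalibrationError("distance must be non-negative")
    point = fit.predict_point(x)
    if fixed_halfwidth is not None:
        if fixed_halfwidth < 0:
            raise CalibrationError("fixed halfwidth must be non-negative")
        lower, upper = point - fixed_halfwidth, point + fixed_halfwidth
        method = f"fixed_halfwidth_{fixed_halfwidth:g}"
    elif interval == "none":
        lower = upper = point
        method = "none"
    elif interval == "prediction":
        if fit.x is None or fit.y is None:
            raise CalibrationError(
                "prediction interval requires a fit carrying its data; "
                "use interval='none' or a fixed halfwidth"
            )
        if fit.n_points < 3:
            raise CalibrationError(
                "prediction interval requires at least 3 calibration points"
            )
        if not 0.0 < level < 1.0:
            raise CalibrationError("level must be in (0, 1)")
        xv, yv = fit.x, fit.y
        n = fit.n_points
        resid = yv - (fit.slope * xv + fit.intercept)
        if fit.mode == "unconstrained":
            dof = n - 2
            s2 = float((resid**2).sum()) / dof
            sxx = float(((xv - xv.mean()) ** 2).sum())
            se = np.sqrt(s2 * (1.0 + 1.0 / n + (x - xv.mean()) ** 2 / sxx))
        else:
            dof = n - 1
            s2 = float((resid**2).sum()) / dof
            sx2 = float((xv**2).sum())
            se = np.sqrt(s2 * (1.0 + x**2 / sx2))
        t = float(stats.t.ppf(0.5 + level / 2.0, dof))
        lower, upper = point - t * se, point + t * se
        method = f"prediction_interval_{level:g}"
    else:
        raise CalibrationError(f"unknown interval method {interval!r}")
    clipped = False
    if lower < 0.0:
        lower, clipped = 0.0, True
    if point < 0.0:
        point, clipped = 0.0, True
    if upper < 0.0:
        upper, clipped = 0.0, True
    return Prediction(
        x_input=float(x),
        point=float(point),
        lower=float(lower),
        upper=float(upper),
        method=method,
        clipped=clipped,
    )


def distance_range_summary(min_pct: float, max_pct: float) -> float:
    """Arithmetic mean of a (min, max) percent-distance range."""
    if min_pct < 0 or max_pct < min_pct:
        raise CalibrationError(
            f"invalid distance range ({min_pct}, {max_pct}): "
            "need 0 <= min <= max"
        )
    return (float(min_pct) + float(max_pct)) / 2.0
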