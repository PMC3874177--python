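"""Prediction-interval differential calling between two conditions.

Per-hotspot integrated signals from one condition are regressed (OLS) on
the other, by default on the log10 scale.  A hotspot outside the two-sided
95% prediction interval

    yhat(x) +/- t_{0.975, n-2} * s * sqrt(1 + 1/n + (x - xbar)^2 / Sxx)

is called increased (above the upper limit) or decreased (below the lower
limit); a point exactly on a limit is inside.  Replication is the error
control: a hotspot is reproducibly changed only when called in the same
direction in every provided comparison.  No multiple-testing correction is
applied beyond the PI-plus-replication rule; with ~288 hotspots roughly 5%
of null points fall outside any single comparison's interval, so single-
comparison calls should never be interpreted alone.

Hotspots with no signal in one condition cannot enter a log-scale
regression; they are handled by the separate de novo detector, which works
on calibrated percent-breakage with a half-threshold guard band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonInput",
    "RegressionFit",
    "fit_comparison",
    "classify_outliers",
    "intersect_reproducible",
    "detect_de_novo",
]


@dataclass(frozen=True)
class ComparisonInput:
    """Paired per-hotspot values for two conditions.

    ``x`` is the reference condition, ``y`` the test condition (arbitrary
    units); ``transform`` is "log10" (default; requires positive values) or
    "linear".
    """

    names: tuple[str, ...]
    x: np.ndarray
    y: np.ndarray
    transform: str = "log10"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if not (len(self.names) == len(self.x) == len(self.y)):
            raise ValueError("names, x and y must have equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 paired values")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("non-finite values in comparison input")
        if self.transform not in ("log10", "linear"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.transform == "log10" and (
            (self.x <= 0).any() or (self.y <= 0).any()
        ):
            raise ValueError(
                "log10 transform requires positive values; route zero-signal "
                "hotspots to de novo detection"
            )

    def transformed(self) -> tuple[np.ndarray, np.ndarray]:
        if self.transform == "log10":
            return np.log10(self.x), np.log10(self.y)
        return self.x.copy(), self.y.copy()


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on x with a two-sided prediction interval."""

    intercept: float
    slope: float
    residual_sd: float
    n: int
    pearson_r: float
    x_mean: float
    sxx: float
    pi_level: float = 0.95

    def prediction_interval(self, x: "float | np.ndarray") -> tuple:
        """(lower, upper) PI limits for a new observation at x."""
        x = np.asarray(x, dtype=float)
        yhat = self.intercept + self.slope * x
        tcrit = stats.t.ppf(0.5 + self.pi_level / 2.0, self.n - 2)
        half = tcrit * self.residual_sd * np.sqrt(
            1.0 + 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        )
        return yhat - half, yhat + half


def fit_comparison(inp: ComparisonInput, pi_level: float = 0.95) -> RegressionFit:
    """OLS of y on x on the transformed scale, with Pearson r."""
    tx, ty = inp.transformed()
    n = len(tx)
    xbar, ybar = tx.mean(), ty.mean()
    sxx = float(np.sum((tx - xbar) ** 2))
    if sxx == 0:
        raise ValueError("zero variance in x; regression undefined")
    sxy = float(np.sum((tx - xbar) * (ty - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = ty - (intercept + slope * tx)
    rss = float(np.sum(resid**2))
    residual_sd = np.sqrt(rss / (n - 2)) if n > 2 else 0.0
    syy = float(np.sum((ty - ybar) ** 2))
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    return RegressionFit(
        intercept=float(intercept),
        slope=float(slope),
        residual_sd=float(residual_sd),
        n=n,
        pearson_r=float(r),
        x_mean=float(xbar),
        sxx=sxx,
        pi_level=pi_level,
    )


def classify_outliers(fit: RegressionFit, inp: ComparisonInput) -> pd.DataFrame:
    """Per-hotspot call table: class increased/decreased/unchanged.

    Classes follow the PI rule on the transformed scale; points exactly on
    a limit are unchanged (closed interval).
    """
    tx, ty = inp.transformed()
    lower, upper = fit.prediction_interval(tx)
    cls = np.where(ty > upper, "increased",
                   np.where(ty < lower, "decreased", "unchanged"))
    return pd.DataFrame(
        {
            "name": list(inp.names),
            "x": inp.x,
            "y": inp.y,
            "residual": ty - (fit.intercept + fit.slope * tx),
            "pi_lower": lower,
            "pi_upper": upper,
            "class": cls,
        }
    )


def intersect_reproducible(calls: "list[pd.DataFrame]") -> pd.DataFrame:
    """Hotspots called in the same direction in every comparison.

    Input call tables must cover the same hotspot universe.  Returns one
    row per hotspot with per-comparison classes and the reproducible class
    ("increased"/"decreased" when unanimous, else "unchanged").
    """
    if len(calls) < 2:
        raise ValueError("need at least 2 call sets")
    base = set(calls[0]["name"])
    for c in calls[1:]:
        if set(c["name"]) != base:
            raise ValueError("call sets cover different hotspot universes")
    merged = calls[0][["name", "class"]].rename(columns={"class": "class_0"})
    for i, c in enumerate(calls[1:], start=1):
        merged = merged.merge(
            c[["name", "class"]].rename(columns={"class": f"class_{i}"}),
            on="name",
        )
    cols = [f"class_{i}" for i in range(len(calls))]
    cls = merged[cols].to_numpy()
    unanimous_inc = (cls == "increased").all(axis=1)
    unanimous_dec = (cls == "decreased").all(axis=1)
    merged["reproducible_class"] = np.where(
        unanimous_inc, "increased", np.where(unanimous_dec, "decreased", "unchanged")
    )
    return merged


def detect_de_novo(
    table_new: pd.DataFrame,
    table_ref: pd.DataFrame,
    threshold: float = 0.3,
) -> list[str]:
    """Hotspots present in one condition but absent in the other.

    A hotspot is de novo in the "new" condition when its percent breakage
    exceeds ``threshold`` there while staying below ``threshold / 2`` in
    the reference condition; the half-threshold guard band avoids boundary
    flicker for hotspots hovering near the cutoff.  Both tables need
    name and percent_breakage columns over the same hotspot universe.
    """
    a = table_new.set_index("name")["percent_breakage"]
    b = table_ref.set_index("name")["percent_breakage"]
    if set(a.index) != set(b.index):
        raise ValueError("tables cover different hotspot universes")
    b = b.reindex(a.index)
    called = a.index[(a > threshold) & (b < threshold / 2.0)]
    return list(called)
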