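"""ChIP-chip tiling-array normalization, calibration and integration.

The pipeline mirrors standard practice for enrichment arrays: per-probe
IP/WCE ratios are divided by the genome median (so cold background sits at
ratio 1), arrays are put on a common scale by multiplying their log10
ratios by a factor fitted over six prominent reference hotspots against the
array with the highest signal there, signal is integrated over hotspot
intervals as above-baseline linear ratio times probe width, and integrated
signal is converted to percent DNA breakage through a through-origin linear
calibration against Southern-blot measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "NormalizedProfile",
    "ReferenceSet",
    "CalibrationModel",
    "normalize_profile",
    "select_reference_profile",
    "fit_scale_factor",
    "integrate_hotspots",
    "calibrate_breakage",
]


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with a name."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"interval {self.name}: end must exceed start")
        if self.start < 0:
            raise ValueError(f"interval {self.name}: negative start")


@dataclass
class NormalizedProfile:
    """Median-normalized per-probe enrichment track.

    ``probes`` has columns chrom/start/end/ratio/log_ratio, where ratio is
    (ip/wce) divided by the genome median of ip/wce (so median(ratio) = 1)
    and log_ratio = log10(ratio).  ``scale_factor`` multiplies log_ratio
    when converting back to the linear scale (1.0 until a cross-array scale
    fit is applied).
    """

    probes: pd.DataFrame
    scale_factor: float = 1.0
    label: str = ""

    def scaled_ratio(self) -> np.ndarray:
        """Linear ratio after applying the log-scale factor."""
        if self.scale_factor == 1.0:
            return self.probes["ratio"].to_numpy()
        return 10.0 ** (self.scale_factor * self.probes["log_ratio"].to_numpy())

    def with_scale(self, c: float) -> "NormalizedProfile":
        if c <= 0:
            raise ValueError("scale factor must be > 0")
        return replace(self, scale_factor=c)


@dataclass(frozen=True)
class ReferenceSet:
    """Six prominent hotspot intervals used for cross-array calibration."""

    intervals: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if len(self.intervals) != 6:
            raise ValueError(
                f"reference set needs exactly six intervals; got "
                f"{len(self.intervals)}"
            )


@dataclass(frozen=True)
class CalibrationModel:
    """Through-origin linear map from integrated signal to % breakage."""

    slope: float
    n_pairs: int
    residual_sd: float


def normalize_profile(probes: pd.DataFrame, label: str = "") -> NormalizedProfile:
    """Median-normalize per-probe IP/WCE ratios.

    ``probes`` must have columns chrom/start/end/ip/wce with all wce > 0.
    The returned ratios have genome median exactly 1; normalization is
    idempotent.
    """
    required = {"chrom", "start", "end", "ip", "wce"}
    missing = required - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    if len(probes) == 0:
        raise ValueError("empty probe table")
    wce = probes["wce"].to_numpy(dtype=float)
    bad = np.flatnonzero(wce <= 0)
    if bad.size:
        row = probes.iloc[bad[0]]
        raise ValueError(
            f"non-positive WCE at probe {row['chrom']}:{row['start']}-{row['end']}"
        )
    raw = probes["ip"].to_numpy(dtype=float) / wce
    med = np.median(raw)
    if med <= 0:
        raise ValueError("genome median of ip/wce is not positive")
    ratio = raw / med
    out = probes[["chrom", "start", "end"]].copy()
    out["ratio"] = ratio
    with np.errstate(divide="ignore"):
        out["log_ratio"] = np.log10(ratio)
    return NormalizedProfile(probes=out, scale_factor=1.0, label=label)


def _refset_means(profile: NormalizedProfile, refset: ReferenceSet) -> np.ndarray:
    """Mean log_ratio within each reference interval (midpoint rule)."""
    p = profile.probes
    mids = (p["start"].to_numpy() + p["end"].to_numpy()) / 2.0
    chroms = p["chrom"].to_numpy()
    lr = p["log_ratio"].to_numpy()
    means = []
    for iv in refset.intervals:
        sel = (chroms == iv.chrom) & (mids >= iv.start) & (mids < iv.end)
        if not sel.any():
            raise ValueError(
                f"profile {profile.label!r} has no probes in reference "
                f"interval {iv.name}"
            )
        means.append(lr[sel].mean())
    return np.asarray(means)


def select_reference_profile(
    profiles: "list[NormalizedProfile]", refset: ReferenceSet
) -> int:
    """Index of the array with the highest mean log-ratio over the refset.

    Ties break in favor of the earliest profile.
    """
    if not profiles:
        raise ValueError("no profiles given")
    scores = [float(_refset_means(p, refset).mean()) for p in profiles]
    return int(np.argmax(scores))


def fit_scale_factor(
    profile: NormalizedProfile,
    reference: NormalizedProfile,
    refset: ReferenceSet,
) -> float:
    """Least-squares log-scale factor matching a profile to the reference.

    Minimizes ``sum_k (c * s_k - r_k)^2`` over the six reference hotspots,
    where s_k and r_k are mean log ratios of the target and reference
    profile within interval k; closed form ``c = sum(r s) / sum(s^2)``.
    A warning is emitted when c falls outside [1.0, 1.5], the plausible
    range for arrays that only need modest rescaling.
    """
    s = _refset_means(profile, refset)
    r = _refset_means(reference, refset)
    denom = float(np.sum(s * s))
    if denom == 0:
        raise ValueError("target profile has zero signal at every reference "
                         "interval; scale factor undefined")
    c = float(np.sum(r * s) / denom)
    if not 1.0 <= c <= 1.5:
        warnings.warn(
            f"fitted scale factor {c:.3f} outside the expected [1.0, 1.5] range",
            stacklevel=2,
        )
    return c


def integrate_hotspots(
    profile: NormalizedProfile, intervals: "list[Interval]"
) -> pd.DataFrame:
    """Integrated above-baseline signal per hotspot interval.

    ``integrated_signal = sum over in-interval probes of
    max(scaled_ratio - 1, 0) * probe_width`` (bp x fold-above-baseline),
    with probes assigned by the midpoint rule.  Intervals without probes
    get NaN signal and a warning.
    """
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"intervals {a.name} and {b.name} overlap")
    p = profile.probes
    mids = (p["start"].to_numpy() + p["end"].to_numpy()) / 2.0
    widths = (p["end"].to_numpy() - p["start"].to_numpy()).astype(float)
    chroms = p["chrom"].to_numpy()
    above = np.clip(profile.scaled_ratio() - 1.0, 0.0, None) * widths
    rows = []
    for iv in intervals:
        sel = (chroms == iv.chrom) & (mids >= iv.start) & (mids < iv.end)
        if not sel.any():
            warnings.warn(f"interval {iv.name} contains no probes", stacklevel=2)
            signal = np.nan
        else:
            signal = float(above[sel].sum())
        rows.append(
            {
                "name": iv.name,
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "integrated_signal": signal,
            }
        )
    return pd.DataFrame(rows)


def calibrate_breakage(
    table: pd.DataFrame,
    southern_pairs: "list[tuple[str, float]]",
    threshold: float = 0.3,
) -> tuple[CalibrationModel, pd.DataFrame]:
    """Fit % breakage = slope x integrated_signal and apply it to the table.

    ``southern_pairs`` are (hotspot name, percent DNA broken) measured by
    Southern blot; the fit is least squares through the origin (zero signal
    means zero breakage).  Adds percent_breakage and passes_threshold
    (percent_breakage > threshold) columns.
    """
    pairs = pd.DataFrame(southern_pairs, columns=["name", "percent"])
    merged = pairs.merge(table[["name", "integrated_signal"]], on="name")
    merged = merged[merged["integrated_signal"] > 0]
    if len(merged) < 2:
        raise ValueError("need at least 2 calibration pairs with positive signal")
    x = merged["integrated_signal"].to_numpy(dtype=float)
    y = merged["percent"].to_numpy(dtype=float)
    slope = float(np.sum(x * y) / np.sum(x * x))
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope ({slope:.3g})")
    resid = y - slope * x
    model = CalibrationModel(
        slope=slope,
        n_pairs=int(len(merged)),
        residual_sd=float(resid.std(ddof=1)) if len(merged) > 1 else 0.0,
    )
    out = table.copy()
    out["percent_breakage"] = slope * out["integrated_signal"]
    out["passes_threshold"] = out["percent_breakage"] > threshold
    return model, out
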