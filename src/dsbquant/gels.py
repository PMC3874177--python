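"""Windowed densitometry of Southern-blot lanes and 2D gels.

One-dimensional lane traces carry named band windows (parental, DSB
fragments, recombinant restriction fragments R1/R2); two-dimensional grids
carry named spot windows (linear arc, Y-shaped novel species NS, intersister
and interhomolog Holliday-junction spots).  All quantities are reported as
fractions of total lane/grid signal, so results are invariant to overall
exposure.  Background is removed per window: a straight baseline between the
window-edge intensities in 1D, a local median from a ring around the window
in 2D.  Negative background-subtracted areas are clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandWindow",
    "LaneProfile",
    "BandQuantResult",
    "SpotWindow",
    "TwoDGrid",
    "TimeCourseQuant",
    "quantify_lane",
    "crossover_frequency",
    "quantify_2d_spots",
    "timecourse_ratios",
]

#: recognised 1D band roles
LANE_ROLES = ("parental", "dsb", "R1", "R2", "other")
#: recognised 2D spot roles
GRID_ROLES = ("linear", "NS", "IS", "IH_small", "IH_large")


@dataclass(frozen=True)
class BandWindow:
    """Named position range [start, end) on a lane with a biological role."""

    name: str
    start: float
    end: float
    role: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window {self.name}: end must exceed start")
        if self.role not in LANE_ROLES:
            raise ValueError(f"window {self.name}: unknown role {self.role!r}")


@dataclass
class LaneProfile:
    """1D densitometry trace with named band windows.

    ``positions`` are migration positions in arbitrary units (monotone
    increasing); ``intensity`` is the non-negative trace.
    """

    positions: np.ndarray
    intensity: np.ndarray
    windows: tuple[BandWindow, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.positions.shape != self.intensity.shape:
            raise ValueError("positions and intensity must have equal length")
        lo, hi = self.positions[0], self.positions[-1]
        wins = sorted(self.windows, key=lambda w: w.start)
        for w in wins:
            if w.start < lo or w.end > hi:
                raise ValueError(f"window {w.name} outside trace range")
        for a, b in zip(wins, wins[1:]):
            if b.start < a.end:
                raise ValueError(f"windows {a.name} and {b.name} overlap")

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass(frozen=True)
class BandQuantResult:
    """Per-band background-subtracted areas as fractions of lane total."""

    areas: dict[str, float]
    fractions: dict[str, float]
    roles: dict[str, str]
    lane_total: float
    unassigned_fraction: float

    @property
    def broken_percent(self) -> float:
        """Percent of total lane DNA in DSB-role bands."""
        return 100.0 * sum(
            f for n, f in self.fractions.items() if self.roles[n] == "dsb"
        )

    def fraction_by_role(self, role: str) -> float:
        return sum(f for n, f in self.fractions.items() if self.roles[n] == role)


@dataclass(frozen=True)
class SpotWindow:
    """Named rectangle [x0,x1) x [y0,y1) in grid-index units with a role."""

    name: str
    x0: int
    x1: int
    y0: int
    y1: int
    role: str

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"window {self.name}: empty rectangle")
        if self.role not in GRID_ROLES:
            raise ValueError(f"window {self.name}: unknown role {self.role!r}")

    def overlaps(self, other: "SpotWindow") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )


@dataclass
class TwoDGrid:
    """2D gel intensity matrix with named rectangular spot windows.

    Axis 0 is first-dimension migration, axis 1 second-dimension.
    """

    intensity: np.ndarray
    windows: tuple[SpotWindow, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D matrix")
        nx, ny = self.intensity.shape
        for w in self.windows:
            if w.x0 < 0 or w.y0 < 0 or w.x1 > nx or w.y1 > ny:
                raise ValueError(f"window {w.name} outside grid")
        for i, a in enumerate(self.windows):
            for b in self.windows[i + 1 :]:
                if a.overlaps(b):
                    raise ValueError(f"windows {a.name} and {b.name} overlap")


@dataclass(frozen=True)
class SpotQuantResult:
    """Per-spot volumes as fractions of total grid signal."""

    volumes: dict[str, float]
    fractions: dict[str, float]
    roles: dict[str, str]
    grid_total: float

    @property
    def unassigned_fraction(self) -> float:
        return max(1.0 - sum(self.fractions.values()), 0.0)

    @property
    def hj_percent(self) -> float:
        """Total Holliday-junction signal (IS + IH spots), % of total DNA."""
        return 100.0 * sum(
            f
            for n, f in self.fractions.items()
            if self.roles[n] in ("IS", "IH_small", "IH_large")
        )

    @property
    def ns_percent(self) -> float:
        return 100.0 * self.fraction_by_role("NS")

    @property
    def is_ih_ratio(self) -> float | None:
        """IS volume over total IH volume; None when no IH signal."""
        ih = sum(
            f
            for n, f in self.fractions.items()
            if self.roles[n] in ("IH_small", "IH_large")
        )
        if ih <= 0:
            return None
        is_ = sum(
            f for n, f in self.fractions.items() if self.roles[n] == "IS"
        )
        return is_ / ih

    def fraction_by_role(self, role: str) -> float:
        return sum(f for n, f in self.fractions.items() if self.roles[n] == role)


@dataclass(frozen=True)
class TimeCourseQuant:
    times: tuple[float, ...]
    hj_percent: tuple[float, ...]
    ns_percent: tuple[float, ...]
    hj_ns_ratio: tuple[float | None, ...]
    ratio_nondecreasing: bool


def quantify_lane(lane: LaneProfile) -> BandQuantResult:
    """Background-subtracted band areas and their fractions of lane total.

    A straight baseline interpolated between the intensities at the window
    edges is removed inside each window; negative net signal is clipped to
    zero.  The denominator is the whole-lane integral ("total DNA"),
    including parental signal and anything outside the windows.
    """
    y = lane.intensity
    if (y < 0).any():
        raise ValueError("negative intensities in lane")
    dx = lane.spacing
    total = float(y.sum() * dx)
    if total <= 0:
        raise ValueError("lane has zero total intensity")
    areas: dict[str, float] = {}
    roles: dict[str, str] = {}
    x = lane.positions
    for w in lane.windows:
        mask = (x >= w.start) & (x < w.end)
        if not mask.any():
            areas[w.name] = 0.0
            roles[w.name] = w.role
            continue
        idx = np.flatnonzero(mask)
        xe = x[idx]
        baseline = np.interp(xe, [x[idx[0]], x[idx[-1]]], [y[idx[0]], y[idx[-1]]])
        net = np.clip(y[idx] - baseline, 0.0, None)
        # keep edge samples: with the baseline at the edges the edge terms
        # vanish anyway, and interior signal is fully counted
        areas[w.name] = float(net.sum() * dx)
        roles[w.name] = w.role
    fractions = {n: a / total for n, a in areas.items()}
    assigned = sum(fractions.values())
    return BandQuantResult(
        areas=areas,
        fractions=fractions,
        roles=roles,
        lane_total=total,
        unassigned_fraction=max(1.0 - assigned, 0.0),
    )


def crossover_frequency(results: "BandQuantResult | list[BandQuantResult]") -> float:
    """Percent crossover DNA: 2 x (R2 fraction of total DNA) x 100.

    Only the shorter recombinant fragment R2 is counted (doubled to account
    for its reciprocal partner), because partial digestion can contribute to
    the longer fragment R1.  A list of replicate lane results is averaged.
    """
    if isinstance(results, BandQuantResult):
        results = [results]
    vals = []
    for r in results:
        if "R2" not in r.roles.values():
            raise ValueError("no R2-role window in lane quantification")
        vals.append(200.0 * r.fraction_by_role("R2"))
    return float(np.mean(vals))


def quantify_2d_spots(grid: TwoDGrid, ring_width: int = 4) -> SpotQuantResult:
    """Spot volumes from window sums minus a local median background.

    Background per window is the median pixel intensity in a frame of
    ``ring_width`` pixels around the rectangle (clipped at grid edges),
    multiplied by the window area; net volumes are clipped at zero.
    Fractions are of the total grid signal.
    """
    z = grid.intensity
    total = float(z.sum())
    if total <= 0:
        raise ValueError("grid has zero total intensity")
    nx, ny = z.shape
    volumes: dict[str, float] = {}
    roles: dict[str, str] = {}
    for w in grid.windows:
        rx0, rx1 = max(w.x0 - ring_width, 0), min(w.x1 + ring_width, nx)
        ry0, ry1 = max(w.y0 - ring_width, 0), min(w.y1 + ring_width, ny)
        frame = z[rx0:rx1, ry0:ry1].copy()
        inner = np.zeros_like(frame, dtype=bool)
        inner[w.x0 - rx0 : w.x1 - rx0, w.y0 - ry0 : w.y1 - ry0] = True
        ring = frame[~inner]
        bg = float(np.median(ring)) if ring.size else 0.0
        win = z[w.x0 : w.x1, w.y0 : w.y1]
        vol = float(win.sum() - bg * win.size)
        volumes[w.name] = max(vol, 0.0)
        roles[w.name] = w.role
    fractions = {n: v / total for n, v in volumes.items()}
    return SpotQuantResult(
        volumes=volumes, fractions=fractions, roles=roles, grid_total=total
    )


def timecourse_ratios(
    grids: list[TwoDGrid], times: "list[float]"
) -> TimeCourseQuant:
    """HJ and novel-species fractions over a 2D-gel time course.

    Reports the HJ:NS ratio per timepoint (None where NS signal is absent)
    and whether the ratio is non-decreasing over time, the signature of the
    novel Y-shaped species being consumed faster than HJs.
    """
    if len(grids) < 2:
        raise ValueError("need at least two timepoints")
    if len(grids) != len(times):
        raise ValueError("grids and times must have equal length")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("times must be strictly increasing")
    hj, ns, ratio = [], [], []
    for g in grids:
        q = quantify_2d_spots(g)
        hj.append(q.hj_percent)
        ns.append(q.ns_percent)
        ratio.append(q.hj_percent / q.ns_percent if q.ns_percent > 0 else None)
    defined = [r for r in ratio if r is not None]
    nondec = all(b >= a - 1e-12 for a, b in zip(defined, defined[1:]))
    return TimeCourseQuant(
        times=tuple(times),
        hj_percent=tuple(hj),
        ns_percent=tuple(ns),
        hj_ns_ratio=tuple(ratio),
        ratio_nondecreasing=nondec,
    )
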