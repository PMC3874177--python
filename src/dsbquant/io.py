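"""Readers and writers for the pipeline's plain-text formats.

All interval files use 0-based half-open coordinates (bedGraph/BED
convention).  Probe signal travels either as a pair of 4-column bedGraph
files (one per channel) or as a single 5-column TSV
(chrom/start/end/ip/wce).  Lane traces and 2D grids are TSV matrices with a
key-value sidecar file naming the band/spot windows.  Parsing is strict: a
malformed line aborts with its line number.  Output tables start with a
'#'-prefixed header line listing column names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import Interval
from .gels import BandWindow, LaneProfile, SpotWindow, TwoDGrid

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_calibration_pairs",
    "write_hotspot_table",
    "read_hotspot_table",
    "write_lane",
    "read_lane",
    "write_grid",
    "read_grid",
    "write_json",
]


def _parse_interval_fields(
    fields: "list[str]", path: str, lineno: int
) -> tuple[str, int, int]:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start < 0:
        raise ValueError(f"{path}:{lineno}: negative start coordinate")
    if end <= start:
        raise ValueError(f"{path}:{lineno}: end <= start")
    return chrom, start, end


def _data_lines(path: "str | Path"):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_probe_table(
    path: "str | Path",
    fmt: str = "tsv",
    wce_path: "str | Path | None" = None,
) -> pd.DataFrame:
    """Probe table with columns chrom/start/end/ip/wce, sorted.

    ``fmt="tsv"``: single file with five columns.  ``fmt="bedgraph"``:
    ``path`` holds the IP channel and ``wce_path`` the WCE channel; the two
    files must cover identical intervals.
    """
    if fmt == "tsv":
        rows = []
        for lineno, fields in _data_lines(path):
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            chrom, start, end = _parse_interval_fields(fields, str(path), lineno)
            try:
                ip, wce = float(fields[3]), float(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric signal") from exc
            rows.append((chrom, start, end, ip, wce))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "ip", "wce"])
    elif fmt == "bedgraph":
        if wce_path is None:
            raise ValueError("bedgraph format needs wce_path for the WCE channel")
        ip = _read_bedgraph(path, "ip")
        wce = _read_bedgraph(wce_path, "wce")
        if not ip[["chrom", "start", "end"]].equals(wce[["chrom", "start", "end"]]):
            raise ValueError("IP and WCE bedGraph files cover different intervals")
        df = ip.copy()
        df["wce"] = wce["wce"]
    else:
        raise ValueError(f"unknown probe table format {fmt!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: no probe records")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _read_bedgraph(path: "str | Path", value_name: str) -> pd.DataFrame:
    rows = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns")
        chrom, start, end = _parse_interval_fields(fields, str(path), lineno)
        try:
            value = float(fields[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric signal") from exc
        rows.append((chrom, start, end, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", value_name])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_probe_table(
    df: pd.DataFrame,
    path: "str | Path",
    fmt: str = "tsv",
    wce_path: "str | Path | None" = None,
) -> None:
    """Write a probe table as 5-column TSV or a bedGraph pair."""
    df = df.sort_values(["chrom", "start"], kind="stable")
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("#chrom\tstart\tend\tip\twce\n")
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t"
                    f"{row.ip:.10g}\t{row.wce:.10g}\n"
                )
    elif fmt == "bedgraph":
        if wce_path is None:
            raise ValueError("bedgraph format needs wce_path")
        for p, col in ((path, "ip"), (wce_path, "wce")):
            with open(p, "w") as fh:
                for row in df.itertuples(index=False):
                    fh.write(
                        f"{row.chrom}\t{row.start}\t{row.end}\t"
                        f"{getattr(row, col):.10g}\n"
                    )
    else:
        raise ValueError(f"unknown probe table format {fmt!r}")


def read_intervals_bed(path: "str | Path") -> list[Interval]:
    """Hotspot intervals from BED3+ (optional 4th name column).

    Unnamed intervals get chrom:start-end names; overlapping intervals are
    an error; output is sorted by (chrom, start).
    """
    ivs = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected at least 3 columns")
        chrom, start, end = _parse_interval_fields(fields, str(path), lineno)
        name = (
            fields[3]
            if len(fields) > 3 and fields[3] not in ("", ".")
            else f"{chrom}:{start}-{end}"
        )
        ivs.append(Interval(name=name, chrom=chrom, start=start, end=end))
    ivs.sort(key=lambda i: (i.chrom, i.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"{path}: intervals {a.name} and {b.name} overlap")
    return ivs


def write_intervals_bed(
    intervals: "list[Interval]",
    path: "str | Path",
    extra: pd.DataFrame | None = None,
) -> None:
    """BED4 (+ optional extra columns joined by interval name)."""
    rows = pd.DataFrame(
        [(i.chrom, i.start, i.end, i.name) for i in intervals],
        columns=["chrom", "start", "end", "name"],
    )
    if extra is not None:
        rows = rows.merge(extra, on="name", how="left")
    rows = rows.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(rows.columns) + "\n")
        rows.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_calibration_pairs(path: "str | Path") -> list[tuple[str, float]]:
    """TSV of (hotspot_name, percent_broken) Southern-blot pairs."""
    pairs = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        try:
            pairs.append((fields[0], float(fields[1])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric percentage") from exc
    return pairs


_HOTSPOT_COLUMNS = [
    "name", "chrom", "start", "end",
    "integrated_signal", "percent_breakage", "passes_threshold",
]


def write_hotspot_table(table: pd.DataFrame, path: "str | Path") -> None:
    cols = [c for c in _HOTSPOT_COLUMNS if c in table.columns]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        table[cols].to_csv(
            fh, sep="\t", header=False, index=False, float_format="%.10g"
        )


def read_hotspot_table(path: "str | Path") -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
        df = pd.read_csv(fh, sep="\t", names=header)
    return df


def _windows_meta(windows) -> dict:
    return {
        w.name: {
            k: getattr(w, k)
            for k in ("start", "end", "role")
            if hasattr(w, k)
        }
        | (
            {k: getattr(w, k) for k in ("x0", "x1", "y0", "y1")}
            if hasattr(w, "x0")
            else {}
        )
        for w in windows
    }


def write_lane(lane: LaneProfile, path: "str | Path", meta_path: "str | Path") -> None:
    """Lane trace as 2-column TSV plus a key-value window sidecar."""
    with open(path, "w") as fh:
        fh.write("#position\tintensity\n")
        for p, v in zip(lane.positions, lane.intensity):
            fh.write(f"{p:.10g}\t{v:.10g}\n")
    meta = {"windows": _windows_meta(lane.windows), "meta": _jsonable(lane.meta)}
    Path(meta_path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_lane(path: "str | Path", meta_path: "str | Path") -> LaneProfile:
    arr = np.loadtxt(path, delimiter="\t", comments="#")
    meta = json.loads(Path(meta_path).read_text())
    windows = tuple(
        BandWindow(name=n, start=w["start"], end=w["end"], role=w["role"])
        for n, w in sorted(meta["windows"].items())
    )
    return LaneProfile(
        positions=arr[:, 0],
        intensity=arr[:, 1],
        windows=windows,
        meta=meta.get("meta", {}),
    )


def write_grid(grid: TwoDGrid, path: "str | Path", meta_path: "str | Path") -> None:
    """2D grid as a TSV matrix plus a key-value window sidecar."""
    np.savetxt(path, grid.intensity, delimiter="\t", fmt="%.10g")
    meta = {"windows": _windows_meta(grid.windows), "meta": _jsonable(grid.meta)}
    Path(meta_path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_grid(path: "str | Path", meta_path: "str | Path") -> TwoDGrid:
    z = np.loadtxt(path, delimiter="\t")
    meta = json.loads(Path(meta_path).read_text())
    windows = tuple(
        SpotWindow(
            name=n, x0=w["x0"], x1=w["x1"], y0=w["y0"], y1=w["y1"], role=w["role"]
        )
        for n, w in sorted(meta["windows"].items())
    )
    return TwoDGrid(intensity=z, windows=windows, meta=meta.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path: "str | Path") -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True) + "\n")
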