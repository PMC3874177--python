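"""End-to-end workflow: normalize -> scale -> integrate -> calibrate -> call.

The pipeline consumes one IP/WCE probe table per (condition, replicate)
array, a hotspot interval list, a six-hotspot reference set for cross-array
scaling, and Southern-blot calibration pairs.  It produces per-array
hotspot tables in percent-DNA-broken units, per-replicate differential
comparisons with 95% prediction intervals, the reproducible call set, de
novo hotspot calls, and a run report whose counts match the emitted tables.
Given the same inputs and seed the outputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .arrays import (
    Interval,
    ReferenceSet,
    calibrate_breakage,
    fit_scale_factor,
    integrate_hotspots,
    normalize_profile,
    select_reference_profile,
)
from .differential import (
    ComparisonInput,
    classify_outliers,
    detect_de_novo,
    fit_comparison,
    intersect_reproducible,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "run_scenario_pipeline"]

CONDITIONS = ("A", "B")


@dataclass
class ArrayInput:
    condition: str
    replicate: int
    path: str
    fmt: str = "tsv"
    wce_path: str | None = None


@dataclass
class PipelineConfig:
    """Paths and options for a file-based pipeline run."""

    arrays: list[ArrayInput]
    intervals_bed: str
    calibration_tsv: str
    refset_names: list[str]
    out_dir: str
    pi_level: float = 0.95
    breakage_threshold: float = 0.3
    transform: str = "log10"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.pi_level < 1:
            raise ValueError("pi_level must be in (0, 1)")
        if self.breakage_threshold <= 0:
            raise ValueError("breakage_threshold must be > 0")

    @classmethod
    def from_file(cls, path: "str | Path") -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        data["arrays"] = [ArrayInput(**a) for a in data["arrays"]]
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "arrays": [vars(a) for a in self.arrays],
                "intervals_bed": self.intervals_bed,
                "calibration_tsv": self.calibration_tsv,
                "refset_names": self.refset_names,
                "pi_level": self.pi_level,
                "breakage_threshold": self.breakage_threshold,
                "transform": self.transform,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage summary of a pipeline run."""

    seed: int
    config_hash: str
    n_arrays: int
    n_hotspots: int
    scale_factors: dict
    calibration: dict
    passing_counts: dict
    pearson_r: dict
    n_increased: int
    n_decreased: int
    n_de_novo: int
    increased: list
    decreased: list
    de_novo: list

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_arrays": self.n_arrays,
            "n_hotspots": self.n_hotspots,
            "scale_factors": self.scale_factors,
            "calibration": self.calibration,
            "passing_counts": self.passing_counts,
            "pearson_r": self.pearson_r,
            "n_increased": self.n_increased,
            "n_decreased": self.n_decreased,
            "n_de_novo": self.n_de_novo,
            "increased": self.increased,
            "decreased": self.decreased,
            "de_novo": self.de_novo,
        }


def _core(
    probe_tables: dict,
    intervals: "list[Interval]",
    refset_names: "list[str]",
    southern_pairs: "list[tuple[str, float]]",
    pi_level: float = 0.95,
    threshold: float = 0.3,
    transform: str = "log10",
    seed: int = 0,
    config_hash: str = "",
) -> dict:
    """Shared pipeline core over in-memory probe tables.

    ``probe_tables`` maps (condition, replicate) to chrom/start/end/ip/wce
    DataFrames; conditions "A" (reference, x axis) and "B" (test, y axis).
    """
    if not intervals:
        raise ValueError("empty hotspot interval list")
    by_name = {iv.name: iv for iv in intervals}
    missing = [n for n in refset_names if n not in by_name]
    if missing:
        raise ValueError(f"reference hotspots absent from interval list: {missing}")
    refset = ReferenceSet(intervals=tuple(by_name[n] for n in refset_names))

    keys = sorted(probe_tables)
    profiles = {
        k: normalize_profile(probe_tables[k], label=f"{k[0]}{k[1]}") for k in keys
    }
    ref_idx = select_reference_profile([profiles[k] for k in keys], refset)
    reference = profiles[keys[ref_idx]]
    scale_factors = {}
    for k in keys:
        c = fit_scale_factor(profiles[k], reference, refset)
        profiles[k] = profiles[k].with_scale(c)
        scale_factors[k] = c

    tables = {k: integrate_hotspots(profiles[k], intervals) for k in keys}

    model, _ = calibrate_breakage(
        tables[keys[ref_idx]], southern_pairs, threshold=threshold
    )
    for k in keys:
        t = tables[k]
        t["percent_breakage"] = model.slope * t["integrated_signal"]
        t["passes_threshold"] = t["percent_breakage"] > threshold
        tables[k] = t

    mean_tables = {}
    for cond in CONDITIONS:
        reps = [tables[k] for k in keys if k[0] == cond]
        if not reps:
            continue
        m = reps[0][["name", "chrom", "start", "end"]].copy()
        m["percent_breakage"] = (
            sum(t["percent_breakage"].to_numpy() for t in reps) / len(reps)
        )
        m["integrated_signal"] = (
            sum(t["integrated_signal"].to_numpy() for t in reps) / len(reps)
        )
        m["passes_threshold"] = m["percent_breakage"] > threshold
        mean_tables[cond] = m

    passing_counts = {
        cond: int(mean_tables[cond]["passes_threshold"].sum())
        for cond in mean_tables
    }
    if len(mean_tables) == 2:
        union = (
            mean_tables["A"]["passes_threshold"].to_numpy()
            | mean_tables["B"]["passes_threshold"].to_numpy()
        )
        passing_counts["union"] = int(union.sum())

    results = {
        "profiles": profiles,
        "tables": tables,
        "mean_tables": mean_tables,
        "scale_factors": scale_factors,
        "calibration": model,
        "passing_counts": passing_counts,
        "reference_key": keys[ref_idx],
    }
    if len(mean_tables) < 2:
        return results

    # universe for the log-scale regression: hotspots above threshold in the
    # replicate-mean of both conditions, positive in every array
    a_m, b_m = mean_tables["A"], mean_tables["B"]
    ok = a_m["passes_threshold"].to_numpy() & b_m["passes_threshold"].to_numpy()
    for k in keys:
        ok &= tables[k]["percent_breakage"].to_numpy() > 0
    universe = a_m["name"].to_numpy()[ok]

    n_pairs = min(
        len([k for k in keys if k[0] == "A"]),
        len([k for k in keys if k[0] == "B"]),
    )
    comparisons = []
    fits = {}
    for rep in range(n_pairs):
        xa = tables[("A", rep)].set_index("name")["percent_breakage"]
        yb = tables[("B", rep)].set_index("name")["percent_breakage"]
        inp = ComparisonInput(
            names=tuple(universe),
            x=xa.loc[universe].to_numpy(),
            y=yb.loc[universe].to_numpy(),
            transform=transform,
        )
        fit = fit_comparison(inp, pi_level=pi_level)
        calls = classify_outliers(fit, inp)
        fits[rep] = fit
        comparisons.append(calls)

    reproducible = intersect_reproducible(comparisons)
    de_novo = detect_de_novo(mean_tables["B"], mean_tables["A"], threshold=threshold)
    increased = sorted(
        reproducible.loc[
            reproducible["reproducible_class"] == "increased", "name"
        ]
    )
    decreased = sorted(
        reproducible.loc[
            reproducible["reproducible_class"] == "decreased", "name"
        ]
    )

    results.update(
        {
            "comparisons": comparisons,
            "fits": fits,
            "reproducible": reproducible,
            "increased": increased,
            "decreased": decreased,
            "de_novo": sorted(de_novo),
        }
    )
    results["report"] = RunReport(
        seed=seed,
        config_hash=config_hash,
        n_arrays=len(keys),
        n_hotspots=len(intervals),
        scale_factors={f"{k[0]}{k[1]}": v for k, v in scale_factors.items()},
        calibration={
            "slope": model.slope,
            "n_pairs": model.n_pairs,
            "residual_sd": model.residual_sd,
        },
        passing_counts=passing_counts,
        pearson_r={str(r): fits[r].pearson_r for r in fits},
        n_increased=len(increased),
        n_decreased=len(decreased),
        n_de_novo=len(results["de_novo"]),
        increased=increased,
        decreased=decreased,
        de_novo=results["de_novo"],
    )
    return results


def run_scenario_pipeline(scenario, out_dir: "str | Path | None" = None) -> dict:
    """Simulate every array of a built scenario and run the full pipeline.

    Convenience entry point used by the examples and the acceptance checks;
    equivalent to writing the simulated arrays to disk and running
    ``run_pipeline`` on them.
    """
    from .synthetic import simulate_array_pair

    probe_tables = {
        (cond, rep): simulate_array_pair(scenario, cond, rep)
        for cond in CONDITIONS
        for rep in range(scenario.n_replicate_pairs)
    }
    intervals = [
        Interval(name=h.name, chrom=h.chrom, start=h.start, end=h.end)
        for h in scenario.hotspots
    ]
    results = _core(
        probe_tables,
        intervals,
        list(scenario.refset_names),
        scenario.southern_pairs(25),
        seed=scenario.seed,
        config_hash="scenario",
    )
    if out_dir is not None:
        _write_outputs(results, Path(out_dir))
    return results


def run_pipeline(config: PipelineConfig) -> RunReport:
    """File-based pipeline run; writes all stage outputs under out_dir."""
    probe_tables = {}
    for a in config.arrays:
        key = (a.condition, a.replicate)
        probe_tables[key] = dio.read_probe_table(
            a.path, fmt=a.fmt, wce_path=a.wce_path
        )
    intervals = dio.read_intervals_bed(config.intervals_bed)
    pairs = dio.read_calibration_pairs(config.calibration_tsv)
    results = _core(
        probe_tables,
        intervals,
        config.refset_names,
        pairs,
        pi_level=config.pi_level,
        threshold=config.breakage_threshold,
        transform=config.transform,
        seed=config.seed,
        config_hash=config.content_hash(),
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_outputs(results, out)
    return results["report"]


def _write_outputs(results: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for k, t in results["tables"].items():
        dio.write_hotspot_table(t, out / f"hotspots_{k[0]}{k[1]}.tsv")
    dio.write_json(
        {
            "slope": results["calibration"].slope,
            "n_pairs": results["calibration"].n_pairs,
            "residual_sd": results["calibration"].residual_sd,
        },
        out / "calibration.json",
    )
    if "reproducible" not in results:
        return
    calls = results["reproducible"].sort_values("name")
    with open(out / "calls.tsv", "w") as fh:
        fh.write("#" + "\t".join(calls.columns) + "\n")
        calls.to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")
    fit_summary = {
        str(rep): {
            "pearson_r": f.pearson_r,
            "slope": f.slope,
            "intercept": f.intercept,
            "residual_sd": f.residual_sd,
            "n": f.n,
        }
        for rep, f in results["fits"].items()
    }
    dio.write_json(fit_summary, out / "fits.json")
    dio.write_json(results["report"].to_dict(), out / "report.json")
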