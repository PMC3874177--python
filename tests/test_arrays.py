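"""Array normalization, scale calibration, integration, breakage calibration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsbquant.arrays import (
    Interval,
    ReferenceSet,
    calibrate_breakage,
    fit_scale_factor,
    integrate_hotspots,
    normalize_profile,
    select_reference_profile,
)


def probe_frame(ratios, spacing=300, wce=1.0):
    n = len(ratios)
    start = np.arange(n) * spacing
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": start,
            "end": start + spacing,
            "ip": np.asarray(ratios, dtype=float) * wce,
            "wce": wce,
        }
    )


class TestNormalize:
    def test_identity_when_ip_equals_wce(self):
        prof = normalize_profile(probe_frame(np.ones(11)))
        assert np.allclose(prof.probes["ratio"], 1.0)
        assert np.allclose(prof.probes["log_ratio"], 0.0)

    def test_median_divides_out(self):
        prof = normalize_profile(probe_frame([1.0, 2.0, 4.0]))
        assert np.allclose(prof.probes["ratio"], [0.5, 1.0, 2.0])

    def test_median_is_one_by_construction(self):
        rng = np.random.default_rng(0)
        prof = normalize_profile(probe_frame(rng.lognormal(0, 1, 101)))
        assert np.median(prof.probes["ratio"]) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        first = normalize_profile(probe_frame(rng.lognormal(0, 0.5, 51)))
        again = normalize_profile(
            first.probes.assign(ip=first.probes["ratio"], wce=1.0)
        )
        assert np.allclose(
            first.probes["ratio"], again.probes["ratio"], atol=1e-12
        )

    def test_nonpositive_wce_names_probe(self):
        df = probe_frame([1.0, 2.0, 3.0])
        df.loc[1, "wce"] = 0.0
        with pytest.raises(ValueError, match="chr1:300-600"):
            normalize_profile(df)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            normalize_profile(probe_frame([]))


def _refset_profiles(c_true, n=600, seed=0):
    """Reference profile with six strong peaks plus a copy whose log ratios
    are divided by c_true."""
    rng = np.random.default_rng(seed)
    ratios = np.ones(n)
    intervals = []
    for k in range(6):
        lo = 50 + 90 * k
        ratios[lo : lo + 10] = 20.0 + 10 * rng.random()
        intervals.append(
            Interval(f"ref{k}", "chr1", lo * 300, (lo + 10) * 300)
        )
    ref = normalize_profile(probe_frame(ratios))
    target_probes = ref.probes.copy()
    target_probes["ip"] = 10.0 ** (target_probes["log_ratio"] / c_true)
    target_probes["wce"] = 1.0
    target = normalize_profile(target_probes)
    return target, ref, ReferenceSet(intervals=tuple(intervals))


class TestScaleFactor:
    def test_identity_profile_gives_unity(self):
        target, ref, rs = _refset_profiles(1.0)
        assert fit_scale_factor(ref, ref, rs) == pytest.approx(1.0, abs=1e-12)

    def test_planted_factor_recovered(self):
        target, ref, rs = _refset_profiles(1.2)
        assert fit_scale_factor(target, ref, rs) == pytest.approx(1.2, abs=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(c=st.floats(min_value=0.5, max_value=2.0))
    def test_recovery_over_planted_range(self, c):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            target, ref, rs = _refset_profiles(c)
            fitted = fit_scale_factor(target, ref, rs)
        assert abs(fitted - c) / c <= 0.01

    def test_warning_outside_plausible_band(self):
        target, ref, rs = _refset_profiles(1.8)
        with pytest.warns(UserWarning, match="outside"):
            fit_scale_factor(target, ref, rs)

    def test_zero_signal_target_rejected(self):
        _, ref, rs = _refset_profiles(1.0)
        flat = normalize_profile(probe_frame(np.ones(600)))
        with pytest.raises(ValueError, match="zero signal"):
            fit_scale_factor(flat, ref, rs)

    def test_reference_selection_prefers_highest(self):
        t12, ref, rs = _refset_profiles(1.2)
        assert select_reference_profile([t12, ref], rs) == 1

    def test_preset_scale_factors_in_printed_range(self, paper_results):
        non_ref = {
            k: v
            for k, v in paper_results["scale_factors"].items()
            if k != paper_results["reference_key"]
        }
        assert all(1.1 <= c <= 1.3 for c in non_ref.values())
        assert paper_results["scale_factors"][
            paper_results["reference_key"]
        ] == pytest.approx(1.0, abs=1e-12)


class TestIntegration:
    def test_flat_profile_zero_signal(self):
        prof = normalize_profile(probe_frame(np.ones(40)))
        table = integrate_hotspots(
            prof, [Interval("h", "chr1", 0, 3000)]
        )
        assert table["integrated_signal"].iloc[0] == 0.0

    def test_rectangular_peak_bruteforce(self):
        # ratio 11 over 3 probes of 300 bp -> (11-1) * 900 = 9000
        ratios = np.ones(101)
        ratios[50:53] = 11.0
        prof = normalize_profile(probe_frame(ratios))
        table = integrate_hotspots(
            prof, [Interval("h", "chr1", 50 * 300, 53 * 300)]
        )
        assert table["integrated_signal"].iloc[0] == pytest.approx(9000.0)

    def test_linearity_in_above_baseline_signal(self):
        ratios = np.ones(101)
        ratios[40:46] = 1.0 + np.array([1, 3, 7, 7, 3, 1], dtype=float)
        doubled = np.ones(101)
        doubled[40:46] = 1.0 + 2 * np.array([1, 3, 7, 7, 3, 1], dtype=float)
        iv = [Interval("h", "chr1", 40 * 300, 46 * 300)]
        s1 = integrate_hotspots(normalize_profile(probe_frame(ratios)), iv)
        s2 = integrate_hotspots(normalize_profile(probe_frame(doubled)), iv)
        assert s2["integrated_signal"].iloc[0] == pytest.approx(
            2 * s1["integrated_signal"].iloc[0]
        )

    def test_interval_without_probes_warns_nan(self):
        prof = normalize_profile(probe_frame(np.ones(10)))
        with pytest.warns(UserWarning, match="no probes"):
            table = integrate_hotspots(
                prof,
                [Interval("far", "chr2", 0, 1000),
                 Interval("ok", "chr1", 0, 900)],
            )
        assert np.isnan(
            table.set_index("name").loc["far", "integrated_signal"]
        )

    def test_overlapping_intervals_rejected(self):
        prof = normalize_profile(probe_frame(np.ones(20)))
        with pytest.raises(ValueError, match="overlap"):
            integrate_hotspots(
                prof,
                [Interval("a", "chr1", 0, 1200),
                 Interval("b", "chr1", 900, 2100)],
            )

    def test_noiseless_scenario_matches_planted_truth(self, paper_scenario):
        """With all noise and gains off, integration reproduces the planted
        per-hotspot integrals exactly (correlation 1 with the truth table)."""
        from dsbquant.synthetic import build_scenario, simulate_array_pair

        quiet = build_scenario(
            genome=paper_scenario.genome,
            hotspots=list(paper_scenario.hotspots),
        )
        df = simulate_array_pair(quiet, "A", 0)
        prof = normalize_profile(df)
        intervals = [
            Interval(h.name, h.chrom, h.start, h.end)
            for h in quiet.hotspots
        ]
        table = integrate_hotspots(prof, intervals).set_index("name")
        truth = quiet.truth.set_index("name")
        present = truth[truth["present_a"]]
        got = table.loc[present.index, "integrated_signal"].to_numpy()
        want = present["integral_a"].to_numpy()
        assert np.allclose(got, want, rtol=1e-9)


class TestBreakageCalibration:
    @staticmethod
    def _table(signals):
        return pd.DataFrame(
            {
                "name": [f"h{i}" for i in range(len(signals))],
                "chrom": "chr1",
                "start": 0,
                "end": 1,
                "integrated_signal": signals,
            }
        )

    def test_exact_line_recovered(self):
        table = self._table(np.linspace(100, 5000, 25))
        pairs = [(f"h{i}", 0.001 * s) for i, s in enumerate(table["integrated_signal"])]
        model, out = calibrate_breakage(table, pairs)
        assert model.slope == pytest.approx(0.001, rel=1e-12)
        assert np.allclose(
            out["percent_breakage"], 0.001 * out["integrated_signal"]
        )

    def test_noisy_slope_recovery_within_5pct(self):
        rng = np.random.default_rng(5)
        signals = rng.uniform(200, 8000, 25)
        table = self._table(signals)
        pairs = [
            (f"h{i}", 0.002 * s * rng.normal(1.0, 0.05))
            for i, s in enumerate(signals)
        ]
        model, _ = calibrate_breakage(table, pairs)
        assert abs(model.slope - 0.002) / 0.002 <= 0.05

    def test_threshold_monotone_in_signal(self):
        table = self._table([10.0, 100.0, 400.0, 1000.0])
        pairs = [("h1", 0.1), ("h3", 1.0)]
        _, out = calibrate_breakage(table, pairs)
        flags = out.sort_values("integrated_signal")["passes_threshold"]
        # once a hotspot passes, every stronger hotspot passes too
        assert flags.is_monotonic_increasing

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            calibrate_breakage(self._table([100.0, 200.0]), [("h0", 0.5)])

    def test_paper_scenario_union_passing_count(self, paper_results):
        assert paper_results["passing_counts"]["union"] == 288
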