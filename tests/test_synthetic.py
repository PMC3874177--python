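"""Generators: planted truth, determinism, noiseless identities."""

import numpy as np
import pandas as pd
import pytest

from dsbquant import gels, synthetic
from dsbquant.genetics import haldane_R
from dsbquant.synthetic import (
    CrossScenario,
    GelKinetics,
    GenomeSpec,
    HotspotSpec,
    TwoDSpotSpec,
    build_scenario,
    simulate_2d_gel,
    simulate_array_pair,
    simulate_cross,
    simulate_lane_timecourse,
)

SMALL_GENOME = GenomeSpec(chrom_lengths=(("chr1", 120_000),), probe_spacing=300)


class TestScenario:
    def test_preset_planted_composition(self, paper_scenario):
        t = paper_scenario.truth
        assert len(t) == 288
        counts = t["category"].value_counts()
        assert counts["increased"] == 11
        assert counts["decreased"] == 6
        assert counts["de_novo"] == 1
        assert counts["reference"] == 6
        assert len(paper_scenario.refset_names) == 6
        # intensities within the allowed hotspot/cold dynamic range
        assert t["intensity"].between(1, 400).all()
        assert t["intensity"].max() > 300

    def test_preset_breakage_above_threshold(self, paper_scenario):
        t = paper_scenario.truth
        stronger = t[["breakage_a", "breakage_b"]].max(axis=1)
        assert (stronger > 0.3).all()

    def test_build_deterministic(self):
        a = build_scenario(preset="paper-emulation", seed=7)
        b = build_scenario(preset="paper-emulation", seed=7)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        ta = simulate_array_pair(a, "B", 1)
        tb = simulate_array_pair(b, "B", 1)
        pd.testing.assert_frame_equal(ta, tb)

    def test_zero_hotspots_flat_truth(self):
        scen = build_scenario(genome=SMALL_GENOME, hotspots=[])
        assert len(scen.truth) == 0
        df = simulate_array_pair(scen, "A", 0)
        assert np.allclose(df["ip"] / df["wce"], 1.0)

    def test_overlapping_hotspots_rejected(self):
        hs = [
            HotspotSpec("h1", "chr1", 1000, 4000, intensity=10),
            HotspotSpec("h2", "chr1", 3000, 6000, intensity=10),
        ]
        with pytest.raises(ValueError, match="overlap"):
            build_scenario(genome=SMALL_GENOME, hotspots=hs)

    def test_effects_length_mismatch_rejected(self):
        hs = [HotspotSpec("h1", "chr1", 1000, 4000, intensity=10)]
        with pytest.raises(ValueError, match="length"):
            build_scenario(genome=SMALL_GENOME, hotspots=hs, effects=[2.0, 3.0])


class TestArraySimulation:
    def test_noiseless_rect_hotspot_ratio_identity(self):
        hs = [HotspotSpec("h1", "chr1", 30_000, 33_000, intensity=10, shape="rect")]
        scen = build_scenario(genome=SMALL_GENOME, hotspots=hs)
        df = simulate_array_pair(scen, "A", 0)
        ratio = (df["ip"] / df["wce"]).to_numpy()
        mids = (df["start"] + df["end"]) / 2
        inside = (mids >= 30_000) & (mids < 33_000)
        assert np.allclose(ratio[inside], 10.0)
        assert np.allclose(ratio[~inside], 1.0)

    def test_noiseless_integral_matches_bruteforce(self):
        hs = [HotspotSpec("h1", "chr1", 30_000, 32_400, intensity=25.0)]
        scen = build_scenario(genome=SMALL_GENOME, hotspots=hs)
        df = simulate_array_pair(scen, "A", 0)
        ratio = (df["ip"] / df["wce"]).to_numpy()
        mids = ((df["start"] + df["end"]) / 2).to_numpy()
        inside = (mids >= 30_000) & (mids < 32_400)
        brute = np.sum((ratio[inside] - 1.0) * 300.0)
        assert brute == pytest.approx(
            scen.truth.loc[0, "integral_a"], rel=1e-12
        )

    def test_replicate_correlation_calibration(self):
        rs = []
        for seed in (1, 2, 3):
            scen = build_scenario(preset="paper-emulation", seed=seed)
            sig = {}
            for rep in (0, 1):
                df = simulate_array_pair(scen, "A", rep)
                ratio = (df["ip"] / df["wce"]).to_numpy()
                mids = ((df["start"] + df["end"]) / 2).to_numpy()
                chroms = df["chrom"].to_numpy()
                vals = []
                for h in scen.hotspots:
                    sel = (
                        (chroms == h.chrom) & (mids >= h.start) & (mids < h.end)
                    )
                    vals.append(np.sum(np.clip(ratio[sel] - 1, 0, None)) * 300)
                sig[rep] = np.asarray(vals)
            ok = (sig[0] > 0) & (sig[1] > 0)
            rs.append(
                np.corrcoef(np.log10(sig[0][ok]), np.log10(sig[1][ok]))[0, 1]
            )
        assert min(rs) >= 0.95

    def test_de_novo_absent_in_reference_condition(self, paper_scenario):
        t = paper_scenario.truth
        dn = t[t["category"] == "de_novo"].iloc[0]
        assert dn["integral_a"] == 0.0
        assert dn["breakage_b"] > 0.3


class TestLaneSimulation:
    def test_pre_onset_single_parental_band(self):
        lanes = simulate_lane_timecourse(GelKinetics(), [2.0])
        q = gels.quantify_lane(lanes[0])
        assert q.broken_percent == 0.0
        assert q.fractions["parental"] == pytest.approx(1.0, abs=1e-6)

    def test_noiseless_roundtrip_planted_fraction(self):
        kin = GelKinetics(max_broken_fraction=(0.03, 0.015, 0.005))
        lane = simulate_lane_timecourse(kin, [kin.dsb_peak])[0]
        q = gels.quantify_lane(lane)
        assert q.broken_percent == pytest.approx(5.0, abs=1e-4)
        for j, f in enumerate((0.03, 0.015, 0.005)):
            assert q.fractions[f"dsb{j + 1}"] == pytest.approx(f, rel=1e-6)

    def test_rad50s_accumulation_monotone(self):
        kin = GelKinetics(rad50S_mode=True)
        lanes = simulate_lane_timecourse(kin, [0, 3, 4, 5, 5.5, 6, 7, 9])
        broken = [gels.quantify_lane(l).broken_percent for l in lanes]
        assert all(b >= a - 1e-9 for a, b in zip(broken, broken[1:]))
        assert broken[-1] > 0

    def test_invalid_fragment_size_rejected(self):
        with pytest.raises(ValueError, match="size"):
            GelKinetics(fragment_sizes=(10.0, -1.0, 2.0),
                        max_broken_fraction=(0.01, 0.01, 0.01))


class TestTwoDSimulation:
    def test_single_spot_conserves_volume(self):
        spots = [TwoDSpotSpec("IS", "IS", 60, 60, 1.0)]
        grid = simulate_2d_gel(spots)
        q = gels.quantify_2d_spots(grid)
        assert q.fractions["IS"] == pytest.approx(1.0, abs=1e-12)

    def test_two_spot_pixel_sum_oracle(self):
        spots = [
            TwoDSpotSpec("IS", "IS", 40, 40, 0.6),
            TwoDSpotSpec("IH_small", "IH_small", 80, 80, 0.4),
        ]
        grid = simulate_2d_gel(spots)
        # independent oracle: raw pixel sums inside the windows, minus the
        # uniform baseline level estimated from a far corner
        z = grid.intensity
        base = z[0, 0]
        for w, expected in zip(grid.windows, (0.6, 0.4)):
            raw = z[w.x0 : w.x1, w.y0 : w.y1]
            vol = raw.sum() - base * raw.size
            assert vol / z.sum() == pytest.approx(expected, rel=1e-9)
        q = gels.quantify_2d_spots(grid)
        assert q.fractions["IS"] == pytest.approx(0.6, abs=1e-12)
        assert q.fractions["IH_small"] == pytest.approx(0.4, abs=1e-12)

    def test_volumes_over_one_rejected(self):
        spots = [TwoDSpotSpec("IS", "IS", 40, 40, 0.7),
                 TwoDSpotSpec("NS", "NS", 80, 80, 0.5)]
        with pytest.raises(ValueError, match="sum"):
            simulate_2d_gel(spots)

    def test_preset_planted_ratios(self):
        spots = synthetic.mbs1_25c_spots()
        planted = {s.name: s.volume for s in spots}
        ih = planted["IH_small"] + planted["IH_large"]
        assert planted["IS"] / ih == pytest.approx(3.0)
        assert 100 * (planted["IS"] + ih) == pytest.approx(2.1)
        assert (planted["IS"] + ih) / planted["NS"] == pytest.approx(1.3)


class TestCrossSimulation:
    def test_zero_distance_never_recombines(self):
        for seed in range(5):
            cs = CrossScenario(n_spores=10_000, true_distance_cM=0.0, seed=seed)
            assert simulate_cross(cs).recombinants == 0

    def test_mean_fraction_matches_inverse_haldane(self):
        # closed-form oracle: R = (1 - exp(-16/50)) / 2 = 0.1369255
        true_R = haldane_R(16.0)
        assert true_R == pytest.approx(0.1369255, abs=1e-6)
        n = 10_000
        fracs = [
            simulate_cross(
                CrossScenario(n_spores=n, true_distance_cM=16.0, seed=s)
            ).fraction
            for s in range(200)
        ]
        se = np.sqrt(true_R * (1 - true_R) / n) / np.sqrt(200)
        assert abs(np.mean(fracs) - true_R) < 3 * se

    def test_intragenic_frequency_scale(self):
        cs = CrossScenario(
            n_spores=1_000_000, intragenic_freq_per_1e6=1200.0, seed=3
        )
        counts = simulate_cross(cs)
        # Poisson-scale sampling error around the planted 1200
        assert abs(counts.recombinants - 1200) < 4 * np.sqrt(1200)
        assert counts.frequency == pytest.approx(counts.recombinants)

    def test_exclusive_parameterization_enforced(self):
        with pytest.raises(ValueError, match="exactly one"):
            CrossScenario(n_spores=100, true_distance_cM=1.0,
                          intragenic_freq_per_1e6=5.0)
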