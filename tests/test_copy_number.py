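"""Log-ratio arithmetic, Gaussian smoothing, and the contiguous-run caller."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_panel, build_probe_map, build_sample
from cnloh.copy_number import (
    CNParams, LogRatioTrack, call_segments, classify_whole_chromosome,
    compute_log_ratio, cn_segments_for_sample, gaussian_smooth,
)
from cnloh.io import Segment
from cnloh.simulate import PlantedEvent, SimulationConfig, simulate_reference_panel, simulate_tumor


class TestLogRatio:
    @pytest.mark.parametrize("sa,sb,expected", [
        (2.0, 2.0, 0.0),      # matches the reference total
        (4.0, 4.0, 1.0),      # doubled
        (1.5, 0.5, -1.0),     # halved
    ])
    def test_ratio_of_totals(self, probe_map_1chr, sa, sb, expected):
        panel = build_panel(probe_map_1chr, ref_a=2.0, ref_b=2.0)
        sample = build_sample(probe_map_1chr, a=sa, b=sb)
        track = compute_log_ratio(sample, panel, probe_map_1chr)
        np.testing.assert_allclose(track.table["raw_log2"], expected, atol=1e-12)

    def test_panel_against_itself_is_zero_everywhere(self, probe_map_1chr):
        panel = build_panel(probe_map_1chr, ref_a=1.3, ref_b=0.6)
        sample = build_sample(probe_map_1chr, a=1.3, b=0.6)
        track = compute_log_ratio(sample, panel, probe_map_1chr)
        np.testing.assert_allclose(track.table["raw_log2"], 0.0, atol=1e-12)

    def test_zero_signal_floored(self, probe_map_1chr):
        panel = build_panel(probe_map_1chr)
        sample = build_sample(probe_map_1chr, a=0.0, b=0.0, genotype="NC")
        track = compute_log_ratio(sample, panel, probe_map_1chr)
        assert (track.table["raw_log2"] == -4.0).all()

    def test_zero_signal_with_floor_disabled_errors(self, probe_map_1chr):
        panel = build_panel(probe_map_1chr)
        sample = build_sample(probe_map_1chr, a=0.0, b=0.0)
        with pytest.raises(ValueError, match="floor"):
            compute_log_ratio(sample, panel, probe_map_1chr,
                              CNParams(log2_floor=-np.inf))


def _track(chrom_values: dict[str, tuple[list[int], list[float]]],
           smoothed: bool = False) -> LogRatioTrack:
    rows = []
    for chrom, (positions, values) in chrom_values.items():
        for i, (p, v) in enumerate(zip(positions, values)):
            rows.append((f"{chrom}_{i}", chrom, p, v))
    df = pd.DataFrame(rows, columns=["probe_id", "chromosome", "position", "raw_log2"])
    if smoothed:
        df["smoothed_log2"] = df["raw_log2"]
    return LogRatioTrack("T1", df)


class TestSmoothing:
    def test_three_probe_kernel_hand_computed(self):
        track = _track({"chr1": ([0, 100_000, 200_000], [0.0, 1.0, 0.0])})
        sm = gaussian_smooth(track).table["smoothed_log2"]
        w = np.exp(-0.5)
        assert sm.iloc[1] == pytest.approx(1.0 / (1.0 + 2 * w), abs=1e-4)
        assert sm.iloc[1] == pytest.approx(0.4519, abs=1e-4)

    def test_constant_track_unchanged(self):
        track = _track({"chr1": (list(range(0, 500_000, 10_000)), [0.7] * 50)})
        sm = gaussian_smooth(track).table["smoothed_log2"]
        np.testing.assert_allclose(sm, 0.7, atol=1e-12)

    def test_single_probe_chromosome_keeps_raw_value(self):
        track = _track({"chr1": ([100], [0.9])})
        assert gaussian_smooth(track).table["smoothed_log2"].iloc[0] == pytest.approx(0.9)

    def test_no_smoothing_across_chromosome_boundary(self):
        track = _track({"chr1": ([0, 10_000], [1.0, 1.0]),
                        "chr2": ([0, 10_000], [-1.0, -1.0])})
        sm = gaussian_smooth(track).table["smoothed_log2"]
        np.testing.assert_allclose(sm, [1.0, 1.0, -1.0, -1.0], atol=1e-12)


def _flat_with_run(n, run_start, run_len, value, spacing=12_000):
    positions = [10_000 + i * spacing for i in range(n)]
    values = [0.0] * n
    for i in range(run_start, run_start + run_len):
        values[i] = value
    return _track({"chr1": (positions, values)}, smoothed=True)


class TestRunCalling:
    def test_25_probe_run_beyond_threshold_called(self):
        track = _flat_with_run(100, 40, 25, -0.4)
        segs = call_segments(track)
        assert len(segs) == 1
        assert segs[0].n_probes == 25
        assert segs[0].direction == "loss"
        assert segs[0].mean_log2 == pytest.approx(-0.4)

    def test_20_probe_run_not_called(self):
        # ">20 contiguous probes" is exclusive: exactly 20 fails
        assert call_segments(_flat_with_run(100, 40, 20, -0.4)) == []

    def test_sub_threshold_run_not_called(self):
        assert call_segments(_flat_with_run(100, 30, 30, -0.29)) == []

    def test_threshold_is_inclusive(self):
        segs = call_segments(_flat_with_run(100, 30, 30, 0.3))
        assert len(segs) == 1 and segs[0].direction == "gain"

    def test_single_interrupting_probe_breaks_the_run(self):
        track = _flat_with_run(100, 40, 25, -0.4)
        track.table.loc[52, ["raw_log2", "smoothed_log2"]] = -0.1
        assert call_segments(track) == []

    def test_optional_gap_merge_restores_interrupted_run(self):
        track = _flat_with_run(100, 40, 25, -0.4)
        track.table.loc[52, ["raw_log2", "smoothed_log2"]] = -0.1
        segs = call_segments(track, CNParams(merge_gap_probes=2,
                                             refine_boundaries=False))
        assert len(segs) == 1 and segs[0].n_probes == 25

    def test_raising_threshold_never_adds_called_probes(self):
        rng = np.random.default_rng(0)
        n = 400
        values = rng.normal(0, 0.5, n).tolist()
        track = _track({"chr1": ([10_000 + 12_000 * i for i in range(n)], values)},
                       smoothed=True)
        called = []
        for tau in (0.2, 0.3, 0.4):
            segs = call_segments(track, CNParams(calling_threshold=tau,
                                                 min_run_probes=2,
                                                 refine_boundaries=False))
            called.append(sum(s.n_probes for s in segs))
        assert called[0] >= called[1] >= called[2]

    def test_segments_sorted_disjoint_and_above_threshold(self):
        cfg = SimulationConfig(n_snps=800, n_chromosomes=2, noise_sd=0.25, seed=42)
        pm, panel = simulate_reference_panel(cfg)
        pos1, pos2 = pm.positions("chr1"), pm.positions("chr2")
        events = [PlantedEvent("chr1", int(pos1[100]), int(pos1[180]), "loss"),
                  PlantedEvent("chr2", int(pos2[300]), int(pos2[400]), "gain")]
        sample, _ = simulate_tumor(panel, pm, events, cfg)
        segs, _, _ = cn_segments_for_sample(sample, panel, pm)
        params = CNParams()
        for s in segs:
            assert s.n_probes >= params.min_run_probes
            assert abs(s.mean_log2) >= params.calling_threshold
            assert (s.mean_log2 < 0) == (s.direction == "loss")
        per_chrom: dict[str, list[Segment]] = {}
        for s in segs:
            per_chrom.setdefault(s.chromosome, []).append(s)
        for chrom_segs in per_chrom.values():
            for a, b in zip(chrom_segs, chrom_segs[1:]):
                assert a.end_bp < b.start_bp


class TestWholeChromosome:
    def _pm(self):
        return build_probe_map({"chr7": list(range(1_000, 1_001_000, 10_000))})  # 100 probes

    def _seg(self, n, direction="loss"):
        return Segment("T1", "chr7", 1_000, 1_000 + n * 10_000, n, -0.5 if direction == "loss" else 0.5, direction)

    def test_full_coverage_is_wcl(self):
        flags = classify_whole_chromosome([self._seg(100)], self._pm())
        assert flags["chr7"] == "WCL"

    def test_half_coverage_is_none(self):
        assert classify_whole_chromosome([self._seg(50)], self._pm())["chr7"] is None

    def test_exactly_90_percent_inclusive(self):
        assert classify_whole_chromosome([self._seg(90)], self._pm())["chr7"] == "WCL"
        assert classify_whole_chromosome([self._seg(89)], self._pm())["chr7"] is None

    def test_gain_coverage_is_wcg(self):
        flags = classify_whole_chromosome([self._seg(95, "gain")], self._pm())
        assert flags["chr7"] == "WCG"


class TestPlantedRecovery:
    def test_50_probe_loss_recovered_with_tight_boundaries(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_snps=500, n_chromosomes=1, noise_sd=0.2,
                                   seed=100 + seed)
            pm, panel = simulate_reference_panel(cfg)
            pos = pm.positions("chr1")
            i0, i1 = 200, 249
            ev = PlantedEvent("chr1", int(pos[i0]), int(pos[i1]), "loss")
            sample, _ = simulate_tumor(panel, pm, [ev], cfg,
                                       rng=np.random.default_rng(200 + seed))
            losses = [s for s in cn_segments_for_sample(sample, panel, pm)[0]
                      if s.direction == "loss"]
            assert len(losses) == 1
            s = losses[0]
            j0 = int(np.searchsorted(pos, s.start_bp))
            j1 = int(np.searchsorted(pos, s.end_bp))
            if abs(j0 - i0) <= 5 and abs(j1 - i1) <= 5:
                hits += 1
        assert hits >= 16  # boundary precision holds in the large majority

    def test_boundary_refinement_removes_smoothing_overshoot(self):
        """Unrefined smoothed runs overshoot each edge by ~0.52 sigma;
        half-amplitude trimming restores probe-level precision."""
        err_refined, err_plain = [], []
        for seed in range(10):
            cfg = SimulationConfig(n_snps=500, n_chromosomes=1, noise_sd=0.2,
                                   seed=300 + seed)
            pm, panel = simulate_reference_panel(cfg)
            pos = pm.positions("chr1")
            i0, i1 = 200, 249
            ev = PlantedEvent("chr1", int(pos[i0]), int(pos[i1]), "loss")
            sample, _ = simulate_tumor(panel, pm, [ev], cfg,
                                       rng=np.random.default_rng(400 + seed))
            for refine, sink in ((True, err_refined), (False, err_plain)):
                segs, _, _ = cn_segments_for_sample(
                    sample, panel, pm, CNParams(refine_boundaries=refine))
                losses = [s for s in segs if s.direction == "loss"]
                assert len(losses) == 1
                j0 = int(np.searchsorted(pos, losses[0].start_bp))
                j1 = int(np.searchsorted(pos, losses[0].end_bp))
                sink.append(abs(j0 - i0) + abs(j1 - i1))
        assert np.mean(err_refined) < np.mean(err_plain)
        assert np.mean(err_plain) > 5       # the systematic overshoot
        assert np.mean(err_refined) <= 4    # refinement removes it

    def test_contaminated_loss_attenuated_but_still_called(self):
        cfg = SimulationConfig(n_snps=500, n_chromosomes=1, noise_sd=0.2,
                               contamination=0.5, seed=77)
        pm, panel = simulate_reference_panel(cfg)
        pos = pm.positions("chr1")
        ev = PlantedEvent("chr1", int(pos[150]), int(pos[349]), "loss")
        sample, _ = simulate_tumor(panel, pm, [ev], cfg)
        segs, _, track = cn_segments_for_sample(sample, panel, pm)
        inside = (track.table["position"] >= ev.start_bp) & (track.table["position"] <= ev.end_bp)
        assert track.table.loc[inside, "smoothed_log2"].mean() == pytest.approx(
            np.log2(0.75), abs=0.05)
        assert any(s.direction == "loss" and s.n_probes >= 100 for s in segs)
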