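"""CNV calling: GC windows, waviness correction (closed form vs grid
oracle), segmentation with SD-undo, threshold state calling, the strict
length filter and cross-sample region compression."""

import numpy as np
import pandas as pd
import pytest

from gbmkit import simulate as sim
from gbmkit.cnv import (
    LrrSegmenter,
    WavinessCorrector,
    autosomal_markers,
    call_states,
    compress_regions,
    filter_cnvs,
    fit_waviness,
    gc_windows,
    segment_lrr,
    segments_to_bed,
)


def _track(lrr, gc=None, pos=None, chrom="1"):
    n = len(lrr)
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n)],
            "chrom": chrom,
            "pos": pos if pos is not None else np.arange(1, n + 1) * 50_000,
            "lrr": np.asarray(lrr, dtype=float),
            "baf": 0.5,
            "gc_fraction": gc if gc is not None else np.full(n, 0.5),
            "is_allelic": True,
        }
    )


class TestGcWindows:
    def test_uniform_source_gives_constant_fraction(self):
        markers = _track(np.zeros(3), pos=[100, 500, 900])
        bins = pd.DataFrame({"chrom": ["1"], "start": [1], "end": [1000], "gc": [0.5]})
        out = gc_windows(bins, markers, window_bp=200)
        assert np.allclose(out["gc_fraction"], 0.5)
        seq = {"1": "GCAT" * 250}  # 50% GC everywhere up to window phase
        out_seq = gc_windows(seq, markers, window_bp=200)
        assert np.allclose(out_seq["gc_fraction"], 0.5, atol=0.01)

    def test_half_gc_boundary_exact_overlap_arithmetic(self):
        # 1 Mb chromosome: left half all GC, right half all AT
        seq = {"1": "G" * 500_000 + "A" * 500_000}
        markers = _track([0.0], pos=[500_001])
        out = gc_windows(seq, markers, window_bp=1_000_000)
        # window [1, 1_000_000]: 500_000 GC of 1_000_000 -> exactly 0.5
        assert out["gc_fraction"].iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_window_truncated_at_chromosome_start(self):
        seq = {"1": "G" * 100 + "A" * 900}
        markers = _track([0.0], pos=[50])
        out = gc_windows(seq, markers, window_bp=200)
        # available span [1, 150]: 100 G of 150 bases
        assert out["gc_fraction"].iloc[0] == pytest.approx(100 / 150)

    def test_marker_outside_bounds_rejected(self):
        seq = {"1": "ACGT" * 10}
        markers = _track([0.0], pos=[100])
        with pytest.raises(ValueError, match="outside sequence bounds"):
            gc_windows(seq, markers, window_bp=10)

    def test_binned_track_weighted_average(self):
        bins = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [1, 501],
                "end": [500, 1000],
                "gc": [0.2, 0.8],
            }
        )
        markers = _track([0.0], pos=[500])
        out = gc_windows(bins, markers, window_bp=500)
        # window [250, 750]: 251 bp at 0.2, 250 bp at 0.8
        expected = (251 * 0.2 + 250 * 0.8) / 501
        assert out["gc_fraction"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestWaviness:
    def test_orthogonal_signal_gives_zero_coefficient(self):
        track = _track([1.0, -1.0, 1.0, -1.0], gc=np.array([0.6, 0.6, 0.4, 0.4]))
        fit, corrected = fit_waviness(track)
        assert fit.coefficient == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(corrected["lrr"], track["lrr"])

    def test_perfectly_explained_wave_removed_entirely(self):
        gc = np.array([0.3, 0.45, 0.5, 0.55, 0.7])
        g = gc - np.median(gc)
        track = _track(0.4 * g, gc=gc)
        fit, corrected = fit_waviness(track)
        assert fit.coefficient == pytest.approx(0.4, abs=1e-12)
        assert fit.variance_after == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(corrected["lrr"], 0.0, atol=1e-12)

    def test_never_increases_variance(self):
        rng = np.random.default_rng(31)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            gc = rng.uniform(0.3, 0.7, 500)
            lrr = rng.normal(0, 0.2, 500) + rng.uniform(-1, 1) * (gc - np.median(gc))
            fit, _ = fit_waviness(_track(lrr, gc=gc))
            assert fit.variance_after <= fit.variance_before + 1e-15

    def test_coefficient_beats_brute_force_grid(self):
        rng = np.random.default_rng(13)
        gc = rng.uniform(0.3, 0.7, 400)
        g = gc - np.median(gc)
        lrr = rng.normal(0, 0.2, 400) + 0.7 * g
        fit, _ = fit_waviness(_track(lrr, gc=gc))
        grid = np.arange(-5.0, 5.0001, 1e-3)
        variances = np.var(lrr[None, :] - grid[:, None] * g[None, :], axis=1)
        best = grid[np.argmin(variances)]
        assert abs(fit.coefficient - best) < 1e-3
        assert fit.variance_after <= variances.min() + 1e-15

    def test_constant_gc_warns_and_passes_through(self):
        track = _track([0.1, 0.2, 0.3], gc=np.full(3, 0.5))
        with pytest.warns(UserWarning, match="constant"):
            fit, corrected = fit_waviness(track)
        assert fit.coefficient == 0.0
        assert np.allclose(corrected["lrr"], track["lrr"])

    def test_per_chromosome_mode_fits_each(self):
        rng = np.random.default_rng(8)
        parts = []
        for chrom, coef in (("1", 0.5), ("2", -0.5)):
            gc = rng.uniform(0.3, 0.7, 200)
            parts.append(_track(coef * (gc - np.median(gc)), gc=gc, chrom=chrom))
        track = pd.concat(parts, ignore_index=True)
        corrector = WavinessCorrector(per_chromosome=True).fit(track)
        assert corrector.coefficient_["1"] == pytest.approx(0.5, abs=1e-10)
        assert corrector.coefficient_["2"] == pytest.approx(-0.5, abs=1e-10)
        assert np.allclose(corrector.transform(track)["lrr"], 0.0, atol=1e-12)


class TestSegmentation:
    def test_constant_signal_single_segment(self):
        track = _track(np.zeros(200))
        segs = segment_lrr(track, seed=0)
        assert len(segs) == 1
        assert segs["n_markers"].iloc[0] == 200

    def test_noiseless_step_split_exactly(self):
        track = _track(np.concatenate([np.zeros(100), np.ones(100)]))
        segs = segment_lrr(track, seed=0)
        assert len(segs) == 2
        assert list(segs["n_markers"]) == [100, 100]
        assert np.allclose(segs["mean_lrr"], [0.0, 1.0])

    def test_small_shift_undone_by_sd_rule(self):
        rng = np.random.default_rng(44)
        x = np.concatenate(
            [
                rng.normal(0.0, 0.2, 100),
                rng.normal(0.05, 0.2, 100),
                rng.normal(1.0, 0.2, 100),
            ]
        )
        segs = segment_lrr(_track(x), undo_sd=3.0, seed=1)
        # |0 - 0.05| is under 3 SEs of the mean difference (~0.085 for
        # 100-marker segments at noise 0.2): that boundary cannot survive
        assert len(segs) == 2
        assert segs["n_markers"].iloc[0] == pytest.approx(200, abs=2)

    def test_tiles_marker_index_space(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.2, 120), rng.normal(-0.8, 0.2, 80)])
        track = _track(x)
        segs = segment_lrr(track, seed=2)
        assert segs["n_markers"].sum() == len(track)
        assert segs["start"].iloc[0] == track["pos"].iloc[0]
        assert segs["end"].iloc[-1] == track["pos"].iloc[-1]
        # contiguous: next start is the marker after the previous end
        pos = track["pos"].to_numpy()
        for i in range(1, len(segs)):
            prev_end_idx = np.searchsorted(pos, segs["end"].iloc[i - 1])
            assert pos[prev_end_idx + 1] == segs["start"].iloc[i]

    def test_short_chromosome_single_segment_with_warning(self):
        track = _track([0.1, 0.2, -0.1])
        with pytest.warns(UserWarning, match="fewer than"):
            segs = segment_lrr(track, min_markers=5, seed=0)
        assert len(segs) == 1

    def test_determinism_with_seed(self, flat_track):
        s1 = segment_lrr(flat_track, seed=7)
        s2 = segment_lrr(flat_track, seed=7)
        pd.testing.assert_frame_equal(s1, s2)


class TestStateCalling:
    def test_boundary_semantics(self):
        segs = pd.DataFrame(
            {
                "chrom": "1",
                "start": 1,
                "end": 2,
                "n_markers": 1,
                "mean_lrr": [-1.2, -1.0, -0.5, -0.3, 0.0, 0.29, 0.3, 0.5, 0.9, 1.1],
            }
        )
        out = call_states(segs)
        assert list(out["state"]) == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_five_state_ladder(self):
        segs = pd.DataFrame(
            {
                "chrom": "1",
                "start": 1,
                "end": 2,
                "n_markers": 1,
                "mean_lrr": [-1.2, -0.5, 0.1, 0.5, 1.1],
            }
        )
        assert list(call_states(segs)["state"]) == [0, 1, 2, 3, 4]

    def test_non_monotone_thresholds_rejected(self):
        segs = pd.DataFrame(
            {"chrom": "1", "start": 1, "end": 2, "n_markers": 1, "mean_lrr": [0.0]}
        )
        with pytest.raises(ValueError, match="strictly increasing"):
            call_states(segs, thresholds=(-1.0, 0.3, -0.3, 0.9))


class TestFilterAndCompress:
    def _segments(self, lengths_mb, state=3, chrom="1"):
        rows, cursor = [], 1
        for mb in lengths_mb:
            length = int(mb * 1_000_000)
            rows.append(
                {
                    "chrom": chrom,
                    "start": cursor,
                    "end": cursor + length - 1,
                    "n_markers": 10,
                    "mean_lrr": 0.5,
                    "state": state,
                }
            )
            cursor += length
        return pd.DataFrame(rows)

    def test_strict_length_filter(self):
        segs = self._segments([0.5, 1.0, 1.5, 3.0])
        out = filter_cnvs(segs, min_length_bp=1_000_000)
        assert list(out["length_bp"]) == [1_500_000, 3_000_000]

    def test_normal_segments_never_reported(self):
        segs = self._segments([2.0, 3.0], state=2)
        assert filter_cnvs(segs).empty

    def test_sub_megabase_gain_excluded(self):
        segs = self._segments([0.8])
        assert filter_cnvs(segs).empty

    def test_single_sample_regions_identical(self):
        segs = self._segments([2.0, 3.0])
        out = compress_regions({"s1": segs})
        assert len(out) == 2
        assert list(out["s1"]) == [3, 3]
        assert list(out["start"]) == list(segs["start"])

    def test_breakpoint_union_three_regions(self):
        a = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [1, 10_000_001],
                "end": [10_000_000, 20_000_000],
                "n_markers": [5, 5],
                "mean_lrr": [0.0, 0.5],
                "state": [2, 3],
            }
        )
        b = pd.DataFrame(
            {
                "chrom": ["1", "1"],
                "start": [1, 15_000_001],
                "end": [15_000_000, 20_000_000],
                "n_markers": [5, 5],
                "mean_lrr": [0.0, -0.5],
                "state": [2, 1],
            }
        )
        out = compress_regions({"a": a, "b": b})
        assert len(out) == 3
        assert list(out["a"]) == [2, 3, 3]
        assert list(out["b"]) == [2, 2, 1]

    def test_identical_segmentations_idempotent(self):
        segs = self._segments([2.0, 3.0])
        out = compress_regions({"a": segs, "b": segs.copy()})
        assert len(out) == 2
        assert list(out["a"]) == list(out["b"])

    def test_inconsistent_chromosomes_rejected(self):
        a = self._segments([2.0], chrom="1")
        b = self._segments([2.0], chrom="2")
        with pytest.raises(ValueError, match="inconsistent chromosome sets"):
            compress_regions({"a": a, "b": b})

    def test_bed_export_is_zero_based_half_open(self):
        segs = self._segments([1.0])
        bed = segments_to_bed(segs)
        assert bed.loc[0, "start"] == 0
        assert bed.loc[0, "end"] == 1_000_000
        assert bed.loc[0, "name"] == 3


class TestEndToEnd:
    def test_planted_segment_recovered_with_state(self):
        truth = sim.CnvTruth(
            segments=(sim.CnvSegment("1", 40_000_001, 45_000_000, 1, -0.5),),
            noise_sd=0.15,
            seed=3,
        )
        track, _ = sim.gen_marker_track({"1": 100_000_000}, 50_000, truth)
        _, corrected = fit_waviness(track)
        called = call_states(segment_lrr(corrected, seed=3))
        report = filter_cnvs(called)
        assert len(report) == 1
        row = report.iloc[0]
        assert row["state"] == 1
        assert abs(row["start"] - 40_000_001) <= 2 * 50_000
        assert abs(row["end"] - 45_000_000) <= 2 * 50_000

    def test_non_autosomal_and_non_allelic_markers_dropped(self):
        track = _track(np.zeros(10))
        track.loc[3, "chrom"] = "X"
        track.loc[5, "is_allelic"] = False
        out = autosomal_markers(track)
        assert len(out) == 8
        assert "X" not in set(out["chrom"])
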