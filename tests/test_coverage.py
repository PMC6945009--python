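"""Windowed depth, normalization, N-gap masking and copy-number segmentation."""

import numpy as np
import pandas as pd
import pytest

from ploidyscan.core_io import DepthTrack, ReferenceIndex, read_depth
from ploidyscan.coverage import (
    mask_artifacts,
    normalize,
    segment,
    window_depth,
)

W = 100_000


def make_track(depths_by_chrom):
    """Constant per-window depths -> a per-position DepthTrack."""
    frames = []
    for chrom, window_depths in depths_by_chrom.items():
        pos = np.arange(1, W * len(window_depths) + 1)
        depth = np.repeat(window_depths, W)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "depth": depth}))
    return DepthTrack(pd.concat(frames, ignore_index=True), kind="per_position")


def make_ref(n_windows_by_chrom, n_gaps=None):
    return ReferenceIndex(
        [(c, n * W) for c, n in n_windows_by_chrom.items()], n_gaps=n_gaps or {}
    )


class TestWindowDepth:
    def test_constant_depth(self):
        win = window_depth(make_track({"c1": [60]}), make_ref({"c1": 1}), W)
        assert win["mean_depth"].tolist() == [60.0]

    def test_half_gap_window(self):
        ref = make_ref({"c1": 2}, {"c1": [(0, W // 2)]})
        win = window_depth(make_track({"c1": [30, 60]}), ref, W)
        assert win["n_fraction"].tolist() == [0.5, 0.0]

    def test_absent_positions_are_zero(self):
        ref = make_ref({"c1": 2})
        track = make_track({"c1": [60]})  # only the first window has data
        win = window_depth(track, ref, W)
        assert win["mean_depth"].tolist() == [60.0, 0.0]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="not in reference"):
            window_depth(make_track({"cX": [60]}), make_ref({"c1": 1}), W)

    def test_binned_input_equivalent(self, tmp_path):
        ref = make_ref({"c1": 3})
        per_pos = window_depth(make_track({"c1": [10, 20, 30]}), ref, W)
        p = tmp_path / "binned.tsv"
        p.write_text(
            "chrom\tstart\tend\tmean_depth\n"
            + "".join(f"c1\t{i*W}\t{(i+1)*W}\t{d}\n" for i, d in enumerate([10, 20, 30]))
        )
        binned = window_depth(read_depth(p), ref, W)
        assert binned["mean_depth"].tolist() == per_pos["mean_depth"].tolist()

    def test_last_window_short(self):
        ref = ReferenceIndex([("c1", W + W // 2)])
        track = make_track({"c1": [60]})
        win = window_depth(track, ref, W)
        assert win["end"].tolist() == [W, W + W // 2]


class TestNormalize:
    def test_median_baseline(self):
        win = window_depth(make_track({"c1": [60, 60, 60, 80]}), make_ref({"c1": 4}), W)
        out = normalize(win)
        assert out["copy_ratio"].tolist() == pytest.approx([1, 1, 1, 80 / 60])

    def test_identity(self):
        win = window_depth(make_track({"c1": [50] * 4}), make_ref({"c1": 4}), W)
        assert normalize(win)["copy_ratio"].tolist() == [1.0] * 4

    def test_gap_dominated_excluded_from_baseline(self):
        ref = make_ref({"c1": 3}, {"c1": [(0, W)]})
        win = window_depth(make_track({"c1": [0, 60, 60]}), ref, W)
        assert normalize(win).attrs["baseline_depth"] == 60

    def test_all_gap_dominated_rejected(self):
        ref = make_ref({"c1": 1}, {"c1": [(0, W)]})
        win = window_depth(make_track({"c1": [0]}), ref, W)
        with pytest.raises(ValueError, match="gap-dominated"):
            normalize(win)

    def test_poisson_tetraploid_ratio(self, rng):
        """Simulated 20x/copy depth: a 4-copy region normalizes to ~4/3 of a
        3-copy baseline."""
        n_base, n_dup = 30, 8
        depth = np.concatenate(
            [rng.poisson(60, n_base * W), rng.poisson(80, n_dup * W)]
        )
        track = DepthTrack(
            pd.DataFrame(
                {"chrom": "c1", "pos": np.arange(1, len(depth) + 1), "depth": depth}
            ),
            kind="per_position",
        )
        win = normalize(window_depth(track, make_ref({"c1": n_base + n_dup}), W))
        dup_ratio = win["copy_ratio"].iloc[n_base:].mean()
        assert dup_ratio == pytest.approx(4 / 3, rel=0.02)


class TestMask:
    @pytest.mark.parametrize(
        "ratio, n_frac, expect",
        [(0.02, 0.9, True), (0.02, 0.0, False), (1.0, 0.9, False)],
    )
    def test_rule(self, ratio, n_frac, expect):
        win = pd.DataFrame(
            {"chrom": ["c1"], "start": [0], "end": [W], "mean_depth": [1.0],
             "n_fraction": [n_frac], "copy_ratio": [ratio]}
        )
        assert mask_artifacts(win)["artifact"].iloc[0] == expect

    def test_artifact_set_shrinks_as_n_min_rises(self, rng):
        win = pd.DataFrame(
            {
                "chrom": "c1",
                "start": np.arange(50) * W,
                "end": (np.arange(50) + 1) * W,
                "mean_depth": 1.0,
                "n_fraction": rng.random(50),
                "copy_ratio": rng.random(50) * 0.3,
            }
        )
        flags = [
            set(np.flatnonzero(mask_artifacts(win, n_min=n)["artifact"]))
            for n in (0.3, 0.5, 0.7, 0.9)
        ]
        for a, b in zip(flags, flags[1:]):
            assert b <= a


def windows_from_ratios(ratios, artifact=None, chrom="c1"):
    n = len(ratios)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * W,
            "end": (np.arange(n) + 1) * W,
            "mean_depth": np.asarray(ratios) * 60,
            "n_fraction": 0.0,
            "copy_ratio": ratios,
            "artifact": artifact if artifact is not None else [False] * n,
        }
    )


class TestSegment:
    def test_duplication_run(self):
        win = windows_from_ratios([1, 1, 1.33, 1.34, 1.33, 1])
        res = segment(win, baseline_ploidy=3, min_seg=2)
        cns = [(s.start, s.end, s.copy_number) for s in res.segments]
        assert cns == [(0, 2 * W, 3), (2 * W, 5 * W, 4), (5 * W, 6 * W, 3)]

    def test_identity(self):
        res = segment(windows_from_ratios([1.0] * 8), 3)
        assert len(res.segments) == 1
        assert res.segments[0].copy_number == 3

    def test_tiling(self):
        win = windows_from_ratios([1, 1, 1, 1.33, 1.33, 1.33, 1.33, 1.33, 1, 1, 1, 1, 1])
        res = segment(win, 3, min_seg=3)
        covered = sorted((s.start, s.end) for s in res.segments)
        assert covered[0][0] == 0 and covered[-1][1] == 13 * W
        for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
            assert e1 == s2

    def test_short_run_absorbed(self):
        win = windows_from_ratios([1] * 6 + [1.33] * 2 + [1] * 6)
        res = segment(win, 3, min_seg=5)
        assert [s.copy_number for s in res.segments] == [3]

    def test_midpoint_tie_prefers_lower_copy(self):
        # 0.5 is exactly midway between 1/3 and 2/3 for a triploid baseline
        win = windows_from_ratios([0.5] * 6)
        res = segment(win, 3)
        assert res.segments[0].copy_number == 1

    def test_artifact_windows_inherit_flank_state(self):
        win = windows_from_ratios(
            [1, 1, 0.0, 0.0, 1, 1], artifact=[False, False, True, True, False, False]
        )
        res = segment(win, 3, min_seg=1)
        assert [s.copy_number for s in res.segments] == [3]
        assert [(a.start, a.end, a.status) for a in res.artifact_segments] == [
            (2 * W, 4 * W, "n_artifact")
        ]

    def test_low_coverage_without_gap_is_real_deletion(self):
        win = windows_from_ratios([1] * 6 + [0.02] * 6 + [1] * 6)
        res = segment(win, 3, min_seg=5)
        assert [s.copy_number for s in res.segments] == [3, 0, 3]
        assert all(s.status == "real" for s in res.segments)

    def test_bad_ploidy_rejected(self):
        with pytest.raises(ValueError):
            segment(windows_from_ratios([1.0]), 0)


class TestSimulatedRecovery:
    def test_duplication_and_artifacts_recovered(self, small_sim):
        """End-to-end on one simulated triploid: tetraploid segment boundaries
        within one window, N-gap windows masked, no spurious real deletions."""
        cfg, out = small_sim
        track = read_depth(out.depth)
        win = mask_artifacts(normalize(window_depth(track, out.ref_index, W)))
        res = segment(win, cfg.baseline_ploidy)
        dup = cfg.duplication
        cn4 = [s for s in res.segments if s.copy_number == 4]
        assert len(cn4) == 1
        assert abs(cn4[0].start - dup[1]) <= W and abs(cn4[0].end - dup[2]) <= W
        assert cn4[0].chrom == dup[0]
        # every simulated N-gap window is flagged and no real copy-0 emitted
        art = {(a.chrom, a.start, a.end) for a in res.artifact_segments}
        assert art == {(c, s, e) for c, s, e in cfg.n_gap_intervals}
        assert not [s for s in res.segments if s.copy_number == 0]
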