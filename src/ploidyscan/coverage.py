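"""Windowed read-depth analysis and copy-number segmentation.

Depth is averaged in fixed windows (100 kb by default, matching the window
used for variant-density tracks), normalized to a genome-wide baseline (the
median of windows not dominated by assembly N-gaps), masked for pseudo
low-coverage artifacts over N-stretches, and quantized to copy-number states
c / baseline_ploidy.  Adjacent windows in the same state are merged into
segments; short runs are absorbed by their flanks.

No HMM is used: copy states are assigned by nearest-state quantization with
midpoint thresholds, which suffices for megabase-scale events on a stable
baseline and keeps every decision inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import DepthTrack, ReferenceIndex

__all__ = [
    "CopySegment",
    "SegmentationResult",
    "window_depth",
    "normalize",
    "mask_artifacts",
    "segment",
]

DEFAULT_WINDOW = 100_000
DEFAULT_LOW_RATIO = 0.15
DEFAULT_N_MIN = 0.5
DEFAULT_MIN_SEG = 5
DEFAULT_C_MAX = 6

#: Columns of the window table produced by this module.
WINDOW_COLUMNS = [
    "chrom", "start", "end", "mean_depth", "n_fraction",
    "copy_ratio", "artifact",
]


@dataclass
class CopySegment:
    """Maximal run of windows in one copy-number state."""

    chrom: str
    start: int
    end: int
    mean_ratio: float
    copy_number: int
    status: str  # "real" | "n_artifact"


@dataclass
class SegmentationResult:
    """Real segments tile each chromosome; artifact segments are the N-gap
    driven window runs they overlap, reported separately."""

    segments: list[CopySegment]
    artifact_segments: list[CopySegment]


def _window_grid(ref: ReferenceIndex, window: int) -> pd.DataFrame:
    rows = []
    for chrom, length in ref.chromosomes:
        starts = np.arange(0, length, window, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_depth(
    track: DepthTrack, ref: ReferenceIndex, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Mean depth and N-gap fraction per fixed-width window.

    Positions absent from a per-position track count as depth 0; the mean is
    therefore total depth / window width.  The last window of a chromosome
    may be shorter.
    """
    lengths = ref.lengths
    for chrom in track.chroms:
        if chrom not in lengths:
            raise ValueError(f"depth track chromosome {chrom!r} not in reference")
    grid = _window_grid(ref, window)
    depth_sum: dict[tuple[str, int], float] = {}
    if track.kind == "per_position":
        for chrom, sub in track.frame.groupby("chrom", sort=False):
            pos0 = sub["pos"].to_numpy() - 1
            if (pos0 < 0).any() or (pos0 >= lengths[chrom]).any():
                raise ValueError(f"depth position outside chromosome {chrom}")
            idx = pos0 // window
            sums = np.bincount(idx, weights=sub["depth"].to_numpy())
            for w, s in enumerate(sums):
                depth_sum[(chrom, w)] = float(s)
    else:
        for chrom, sub in track.frame.groupby("chrom", sort=False):
            if (sub["end"] > lengths[chrom]).any():
                raise ValueError(f"depth bin outside chromosome {chrom}")
            for _, row in sub.iterrows():
                s, e, d = int(row.start), int(row.end), float(row.mean_depth)
                w = s // window
                while s < e:
                    upto = min(e, (w + 1) * window)
                    key = (chrom, w)
                    depth_sum[key] = depth_sum.get(key, 0.0) + d * (upto - s)
                    s, w = upto, w + 1
    out = grid.copy()
    widths = (out["end"] - out["start"]).to_numpy()
    sums = np.array(
        [depth_sum.get((c, s // window), 0.0)
         for c, s in zip(out["chrom"], out["start"])]
    )
    out["mean_depth"] = sums / widths
    out["n_fraction"] = [
        ref.gap_overlap(c, s, e) / (e - s)
        for c, s, e in zip(out["chrom"], out["start"], out["end"])
    ]
    return out


def normalize(windows: pd.DataFrame, max_gap_fraction: float = 0.1) -> pd.DataFrame:
    """Add ``copy_ratio`` = mean_depth / baseline, the baseline being the
    median mean_depth over windows with n_fraction <= ``max_gap_fraction``."""
    usable = windows[windows["n_fraction"] <= max_gap_fraction]
    if usable.empty:
        raise ValueError("all windows are gap-dominated; cannot set a depth baseline")
    baseline = float(usable["mean_depth"].median())
    if baseline <= 0:
        raise ValueError("depth baseline is zero; track appears empty")
    out = windows.copy()
    out["copy_ratio"] = out["mean_depth"] / baseline
    out.attrs["baseline_depth"] = baseline
    return out


def mask_artifacts(
    windows: pd.DataFrame,
    low_ratio: float = DEFAULT_LOW_RATIO,
    n_min: float = DEFAULT_N_MIN,
) -> pd.DataFrame:
    """Flag pseudo low-coverage windows: near-zero copy ratio explained by
    reference N-stretches rather than a real deletion."""
    out = windows.copy()
    out["artifact"] = (out["copy_ratio"] <= low_ratio) & (out["n_fraction"] >= n_min)
    return out


def _assign_states(ratios: np.ndarray, baseline_ploidy: int, c_max: int) -> np.ndarray:
    states = np.arange(0, c_max + 1) / baseline_ploidy
    dist = np.abs(ratios[:, None] - states[None, :])
    # nearest state; a midpoint tie (within rounding) goes to the lower c,
    # conservative against false duplications
    near_min = dist <= dist.min(axis=1, keepdims=True) + 1e-9
    return np.argmax(near_min, axis=1)


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """(start_idx, end_idx_exclusive, value) runs of a 1-D int array."""
    out = []
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        out.append((i, j, int(values[i])))
        i = j
    return out


def _absorb_short_runs(states: np.ndarray, min_seg: int) -> np.ndarray:
    """Reassign interior runs shorter than min_seg to their larger flank.

    Terminal runs (chromosome ends) are kept: they have a single flank, so
    "flanking majority" is undefined and absorbing them would misplace the
    boundary of a real event reaching the end of the assayed region.
    """
    states = states.copy()
    while True:
        runs = _runs(states)
        short = [
            (j, r) for j, r in enumerate(runs[1:-1], start=1)
            if (r[1] - r[0]) < min_seg
        ]
        if not short:
            return states
        # absorb the shortest run first (leftmost on ties) into its larger flank
        j, (s, e, _) = min(short, key=lambda x: (x[1][1] - x[1][0], x[1][0]))
        left, right = runs[j - 1], runs[j + 1]
        new = left[2] if (left[1] - left[0]) >= (right[1] - right[0]) else right[2]
        states[s:e] = new


def segment(
    windows: pd.DataFrame,
    baseline_ploidy: int,
    c_max: int = DEFAULT_C_MAX,
    min_seg: int = DEFAULT_MIN_SEG,
) -> SegmentationResult:
    """Quantize window copy ratios to copy-number states and merge runs.

    Artifact windows never drive a state of their own: they inherit the state
    of the nearest non-artifact window (left preferred) so that N-gap
    pseudo-deletions cannot surface as real copy-0 segments, and each maximal
    artifact run is additionally reported with status ``n_artifact``.
    """
    if baseline_ploidy < 1:
        raise ValueError("baseline_ploidy must be >= 1")
    if "copy_ratio" not in windows or "artifact" not in windows:
        raise ValueError("run normalize() and mask_artifacts() first")
    segments: list[CopySegment] = []
    artifact_segments: list[CopySegment] = []
    for chrom in dict.fromkeys(windows["chrom"]):
        sub = windows[windows["chrom"] == chrom].reset_index(drop=True)
        ratios = sub["copy_ratio"].to_numpy(dtype=float)
        artifact = sub["artifact"].to_numpy(dtype=bool)
        states = _assign_states(ratios, baseline_ploidy, c_max)
        # artifact windows inherit the nearest non-artifact state
        if artifact.any():
            good = np.flatnonzero(~artifact)
            if len(good) == 0:
                states[:] = baseline_ploidy
            else:
                for i in np.flatnonzero(artifact):
                    prev = good[good < i]
                    nxt = good[good > i]
                    states[i] = states[prev[-1]] if len(prev) else states[nxt[0]]
        states = _absorb_short_runs(states, min_seg)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for s, e, state in _runs(states):
            mask = ~artifact[s:e]
            run_ratios = ratios[s:e][mask] if mask.any() else ratios[s:e]
            segments.append(
                CopySegment(
                    chrom=chrom,
                    start=int(starts[s]),
                    end=int(ends[e - 1]),
                    mean_ratio=float(np.mean(run_ratios)),
                    copy_number=state,
                    status="real",
                )
            )
        for s, e, flag in _runs(artifact.astype(int)):
            if flag:
                artifact_segments.append(
                    CopySegment(
                        chrom=chrom,
                        start=int(starts[s]),
                        end=int(ends[e - 1]),
                        mean_ratio=float(np.mean(ratios[s:e])),
                        copy_number=int(states[s]),
                        status="n_artifact",
                    )
                )
    return SegmentationResult(segments=segments, artifact_segments=artifact_segments)


def segments_to_frame(result: SegmentationResult) -> pd.DataFrame:
    rows = [
        (s.chrom, s.start, s.end, s.mean_ratio, s.copy_number, s.status)
        for s in result.segments + result.artifact_segments
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "mean_ratio", "copy_number", "status"],
    )
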