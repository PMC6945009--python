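"""Reference-allele-frequency spectra and ploidy inference.

At a heterozygous site of a k-ploid sample where i of the k chromosome
copies carry the reference allele, the fraction of reads supporting the
reference concentrates around i/k.  The spectrum of AD_ref/(AD_ref+AD_alt)
over many SNVs therefore shows peaks at the modes {i/k : 1 <= i <= k-1};
a triploid shows 1/3 and 2/3, a tetraploid segment 1/4, 1/2 and 3/4.  Ploidy
is inferred by matching detected spectrum peaks against the candidate mode
sets, with a small complexity penalty so that a k whose modes are a superset
of a smaller k's does not win for free.

Sites where the sample is invariant and only the reference assembly deviates
(reference-allele frequency near 0) carry no ploidy signal and are excluded
below ``invariant_cutoff``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .core_io import VariantRecord
from .coverage import CopySegment, SegmentationResult

__all__ = [
    "AFSpectrum",
    "PloidyCall",
    "ref_af",
    "collect_afs",
    "build_spectrum",
    "detect_peaks",
    "infer_ploidy",
    "segment_ploidy",
]

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 100
DEFAULT_SMOOTH_BW = 3
DEFAULT_MIN_PROMINENCE_FRAC = 0.05
DEFAULT_EDGE_EXCLUDE = 0.03
DEFAULT_INVARIANT_CUTOFF = 0.05
DEFAULT_MIN_SITES = 200
DEFAULT_K_MAX = 6
DEFAULT_COMPLEXITY_PENALTY = 1e-4
SCORE_TIE_TOL = 1e-6


@dataclass
class AFSpectrum:
    """Histogram of reference-allele frequencies on [0, 1]."""

    bin_edges: np.ndarray
    counts: np.ndarray
    region_label: str = "global"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())


@dataclass
class PloidyCall:
    """Inferred ploidy for a region with its supporting peak evidence.

    ``n_ref_like`` counts reference-like haplophases: at a site heterozygous
    in exactly the divergent class, the reference allele sits on the
    reference-like copies, so the dominant peak's mode i/k gives i = number
    of reference-like copies and k - i the divergent count.
    """

    region_label: str
    ploidy: int
    peaks: list[tuple[float, float]]
    n_ref_like: int
    n_divergent: int
    fit_score: float
    ambiguous: bool = False
    n_sites: int = 0


def ref_af(
    record: VariantRecord,
    invariant_cutoff: float = DEFAULT_INVARIANT_CUTOFF,
) -> float | None:
    """Reference-allele frequency of one SNV, or None when excluded.

    Excluded: no informative reads, or frequency below ``invariant_cutoff``
    (sample invariant, only the reference deviates — such sites say nothing
    about the sample's ploidy).
    """
    total = record.ad_ref + record.ad_alt
    if total == 0:
        return None
    af = record.ad_ref / total
    if af < invariant_cutoff:
        return None
    return af


def collect_afs(
    records: Iterable[VariantRecord],
    min_support: int = 5,
    invariant_cutoff: float = DEFAULT_INVARIANT_CUTOFF,
    include_indels: bool = False,
) -> np.ndarray:
    """Reference-allele frequencies of usable records (SNVs by default)."""
    vals = []
    for rec in records:
        if rec.vtype != "SNV" and not include_indels:
            continue
        if rec.ad_ref + rec.ad_alt < min_support:
            continue
        af = ref_af(rec, invariant_cutoff=invariant_cutoff)
        if af is not None:
            vals.append(af)
    return np.asarray(vals, dtype=float)


def build_spectrum(
    afs: Sequence[float],
    n_bins: int = DEFAULT_N_BINS,
    region_label: str = "global",
) -> AFSpectrum:
    """Uniform histogram of frequencies on [0, 1]; 1.0 falls in the last bin."""
    afs = np.asarray(afs, dtype=float)
    if afs.size == 0:
        raise ValueError(f"no usable SNVs for region {region_label!r}")
    if (afs < 0).any() or (afs > 1).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    counts, edges = np.histogram(afs, bins=n_bins, range=(0.0, 1.0))
    return AFSpectrum(bin_edges=edges, counts=counts, region_label=region_label)


def detect_peaks(
    spectrum: AFSpectrum,
    smooth_bw: int = DEFAULT_SMOOTH_BW,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    edge_exclude: float = DEFAULT_EDGE_EXCLUDE,
) -> list[tuple[float, float]]:
    """Local maxima of the smoothed spectrum as (location, height).

    Counts are smoothed by a centered moving average of ``smooth_bw`` bins;
    maxima must clear a prominence of ``min_prominence_frac`` x the smoothed
    maximum, and peaks within ``edge_exclude`` of 0 or 1 are dropped.  Peak
    locations are refined to sub-bin precision by parabolic interpolation of
    the smoothed counts around each maximum, so that a mode falling between
    two bin centers is not quantized to either.  Returned sorted by location.
    """
    kernel = np.ones(smooth_bw)
    counts = spectrum.counts.astype(float)
    # normalize by the actual kernel overlap so edges are not pulled down
    smoothed = np.convolve(counts, kernel, mode="same") / np.convolve(
        np.ones_like(counts), kernel, mode="same"
    )
    if smoothed.max() <= 0:
        return []
    idx, _ = find_peaks(smoothed, prominence=min_prominence_frac * smoothed.max())
    centers = spectrum.bin_centers
    bin_width = float(spectrum.bin_edges[1] - spectrum.bin_edges[0])
    peaks = []
    for i in idx:
        loc = float(centers[i])
        if 0 < i < len(smoothed) - 1:
            denom = smoothed[i - 1] - 2 * smoothed[i] + smoothed[i + 1]
            if denom < 0:
                shift = 0.5 * (smoothed[i - 1] - smoothed[i + 1]) / denom
                loc += float(np.clip(shift, -0.5, 0.5)) * bin_width
        if edge_exclude <= loc <= 1 - edge_exclude:
            peaks.append((loc, float(smoothed[i])))
    return sorted(peaks)


def expected_modes(k: int) -> np.ndarray:
    """Heterozygous allele-frequency modes of a k-ploid: {i/k, 1<=i<=k-1}."""
    return np.arange(1, k) / k


def _fit_score(peaks: list[tuple[float, float]], k: int, penalty: float) -> float:
    modes = expected_modes(k)
    dists = [min((loc - modes) ** 2) for loc, _ in peaks]
    return float(np.mean(dists)) + penalty * k


def infer_ploidy(
    afs: Sequence[float],
    k_max: int = DEFAULT_K_MAX,
    region_label: str = "global",
    min_sites: int = DEFAULT_MIN_SITES,
    n_bins: int = DEFAULT_N_BINS,
    smooth_bw: int = DEFAULT_SMOOTH_BW,
    min_prominence_frac: float = DEFAULT_MIN_PROMINENCE_FRAC,
    complexity_penalty: float = DEFAULT_COMPLEXITY_PENALTY,
) -> PloidyCall:
    """Infer ploidy from allele frequencies by peak-to-mode matching.

    For each candidate k in 2..k_max the score is the mean squared distance
    of detected peaks to their nearest expected mode plus ``complexity_penalty``
    x k; the minimizing k wins, ties (within 1e-6) going to the smaller k
    with the call flagged ambiguous.
    """
    afs = np.asarray(afs, dtype=float)
    if afs.size < min_sites:
        raise ValueError(
            f"{region_label}: {afs.size} usable frequencies < min_sites={min_sites}"
        )
    spectrum = build_spectrum(afs, n_bins=n_bins, region_label=region_label)
    peaks = detect_peaks(
        spectrum, smooth_bw=smooth_bw, min_prominence_frac=min_prominence_frac
    )
    if not peaks:
        raise ValueError(f"{region_label}: no allele-frequency peaks detected")
    ks = np.arange(2, k_max + 1)
    scores = np.array([_fit_score(peaks, k, complexity_penalty) for k in ks])
    best_idx = int(np.argmin(scores))
    best_score = scores[best_idx]
    near = np.flatnonzero(np.abs(scores - best_score) <= SCORE_TIE_TOL)
    ambiguous = len(near) > 1
    k = int(ks[near[0]])  # smallest k among ties
    # assign the dominant (highest) peak to its nearest mode i/k
    modes = expected_modes(k)
    top_loc, _ = max(peaks, key=lambda p: p[1])
    n_ref_like = int(np.argmin(np.abs(top_loc - modes))) + 1
    return PloidyCall(
        region_label=region_label,
        ploidy=k,
        peaks=peaks,
        n_ref_like=n_ref_like,
        n_divergent=k - n_ref_like,
        fit_score=float(scores[near[0]]),
        ambiguous=ambiguous,
        n_sites=int(afs.size),
    )


def _segment_af_index(
    records: Iterable[VariantRecord],
    segments: list[CopySegment],
    min_support: int,
    invariant_cutoff: float,
    include_indels: bool,
) -> dict[int, list[float]]:
    by_chrom: dict[str, list[tuple[int, CopySegment]]] = {}
    for i, seg in enumerate(segments):
        by_chrom.setdefault(seg.chrom, []).append((i, seg))
    for segs in by_chrom.values():
        segs.sort(key=lambda x: x[1].start)
    out: dict[int, list[float]] = {i: [] for i in range(len(segments))}
    for rec in records:
        if rec.vtype != "SNV" and not include_indels:
            continue
        if rec.ad_ref + rec.ad_alt < min_support:
            continue
        af = ref_af(rec, invariant_cutoff=invariant_cutoff)
        if af is None:
            continue
        pos0 = rec.pos - 1
        for i, seg in by_chrom.get(rec.chrom, []):
            if seg.start <= pos0 < seg.end:
                out[i].append(af)
                break
    return out


def segment_ploidy(
    records: Iterable[VariantRecord],
    segmentation: SegmentationResult,
    baseline_ploidy: int,
    min_sites: int = DEFAULT_MIN_SITES,
    min_support: int = 5,
    invariant_cutoff: float = DEFAULT_INVARIANT_CUTOFF,
    include_indels: bool = False,
    **infer_kwargs,
) -> tuple[list[PloidyCall], list[dict]]:
    """Per-segment ploidy calls plus a global call over baseline-state windows.

    Each real copy-number segment with at least ``min_sites`` usable SNVs gets
    its own call; segments with fewer are skipped (reported as insufficient).
    A segment call disagreeing with the segment's coverage-derived copy number
    is flagged in the report, never silently altered.
    """
    records = list(records)
    segments = segmentation.segments
    af_index = _segment_af_index(
        records, segments, min_support, invariant_cutoff, include_indels
    )
    global_afs = [
        af
        for i, seg in enumerate(segments)
        if seg.copy_number == baseline_ploidy
        for af in af_index[i]
    ]
    calls: list[PloidyCall] = []
    report: list[dict] = []
    global_call = infer_ploidy(
        global_afs, region_label="global", min_sites=min_sites, **infer_kwargs
    )
    calls.append(global_call)
    report.append(
        {
            "region_label": "global",
            "ploidy": global_call.ploidy,
            "expected_copy_number": baseline_ploidy,
            "consistent": global_call.ploidy == baseline_ploidy,
            "n_sites": global_call.n_sites,
            "status": "called",
        }
    )
    for i, seg in enumerate(segments):
        label = f"{seg.chrom}:{seg.start}-{seg.end}"
        afs = af_index[i]
        if len(afs) < min_sites:
            logger.warning("segment %s skipped: %d SNVs < %d", label, len(afs), min_sites)
            report.append(
                {
                    "region_label": label,
                    "ploidy": None,
                    "expected_copy_number": seg.copy_number,
                    "consistent": None,
                    "n_sites": len(afs),
                    "status": "insufficient sites",
                }
            )
            continue
        call = infer_ploidy(afs, region_label=label, min_sites=min_sites, **infer_kwargs)
        calls.append(call)
        consistent = call.ploidy == seg.copy_number
        if not consistent:
            logger.warning(
                "segment %s: AF ploidy %d != coverage copy number %d",
                label, call.ploidy, seg.copy_number,
            )
        report.append(
            {
                "region_label": label,
                "ploidy": call.ploidy,
                "expected_copy_number": seg.copy_number,
                "consistent": consistent,
                "n_sites": call.n_sites,
                "status": "called",
            }
        )
    return calls, report
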