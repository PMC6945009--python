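"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
VCF positions are 1-based (as in the format); every internal interval and
every BED written by this package is 0-based half-open.  The conversion
happens exactly once, at the I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

__all__ = [
    "ReferenceIndex",
    "VariantRecord",
    "DepthTrack",
    "read_reference",
    "read_vcf",
    "write_vcf",
    "read_depth",
    "read_bed",
    "write_bed",
    "read_tsv",
    "write_tsv",
]

DEFAULT_MIN_GAP = 100


@dataclass
class ReferenceIndex:
    """Chromosome names/lengths, N-gap intervals and optional centromeres.

    ``chromosomes`` is an ordered list of ``(name, length_bp)``; ``n_gaps``
    maps a chromosome to sorted, non-overlapping 0-based half-open intervals
    of ambiguous bases; ``centromeres`` optionally maps a chromosome to a
    point position in bp.
    """

    chromosomes: list[tuple[str, int]]
    n_gaps: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    centromeres: dict[str, int] | None = None

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in reference index")
        lengths = dict(self.chromosomes)
        for chrom, gaps in self.n_gaps.items():
            prev_end = 0
            for start, end in gaps:
                if not (0 <= start < end <= lengths[chrom]):
                    raise ValueError(
                        f"gap [{start},{end}) outside chromosome {chrom}"
                    )
                if start < prev_end:
                    raise ValueError(f"overlapping/unsorted gaps on {chrom}")
                prev_end = end

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def gap_overlap(self, chrom: str, start: int, end: int) -> int:
        """Total bp of N-gap inside [start, end) on ``chrom``."""
        total = 0
        for gs, ge in self.n_gaps.get(chrom, []):
            total += max(0, min(end, ge) - max(start, gs))
        return total


@dataclass
class VariantRecord:
    """One called variant, biallelic after multi-allelic splitting.

    ``pos`` is 1-based.  ``missing`` names any of QD/FS/MQ absent from the
    source record; such records are never silently treated as passing.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qd: float
    fs: float
    mq: float
    ad_ref: int
    ad_alt: int
    dp: int
    missing: tuple[str, ...] = ()

    @property
    def vtype(self) -> str:
        if len(self.ref_allele) == 1 and len(self.alt_allele) == 1:
            return "SNV"
        return "InDel"

    @property
    def indel_length(self) -> int:
        return abs(len(self.alt_allele) - len(self.ref_allele))

    @property
    def support(self) -> int:
        return self.ad_ref + self.ad_alt


@dataclass
class DepthTrack:
    """Read-depth observations, per-position or pre-binned.

    ``kind`` is ``"per_position"`` (columns chrom, pos, depth; pos 1-based as
    produced by ``samtools depth``) or ``"binned"`` (columns chrom, start,
    end, mean_depth; 0-based half-open).  Positions absent from a
    per-position track are depth 0 by convention.
    """

    frame: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("per_position", "binned"):
            raise ValueError(f"unknown depth track kind {self.kind!r}")
        key = "pos" if self.kind == "per_position" else "start"
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            v = sub[key].to_numpy()
            if len(v) > 1 and not (np.diff(v) > 0).all():
                raise ValueError(
                    f"depth positions not strictly increasing on {chrom}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))


# ---------------------------------------------------------------------------
# FASTA


def _n_runs(seq: str, min_gap: int) -> list[tuple[int, int]]:
    """Maximal runs of N (case-insensitive) of length >= min_gap."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
    is_n = arr == b"N"
    if not is_n.any():
        return []
    padded = np.concatenate(([False], is_n, [False]))
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    keep = (ends - starts) >= min_gap
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))


def read_reference(
    fasta_path: str | os.PathLike,
    min_gap: int = DEFAULT_MIN_GAP,
    centromere_bed: str | os.PathLike | None = None,
) -> ReferenceIndex:
    """Index a reference FASTA: lengths plus maximal N-runs >= ``min_gap`` bp.

    Raises on an empty file or duplicate sequence names.
    """
    try:
        fa = Fasta(str(fasta_path), duplicate_action="stop", rebuild=True)
    except Exception as exc:  # pyfaidx: ValueError on duplicates, its own
        raise ValueError(f"bad FASTA {fasta_path}: {exc}") from exc  # errors otherwise
    names = list(fa.keys())
    if not names:
        raise ValueError(f"empty FASTA: {fasta_path}")
    chromosomes = [(name, len(fa[name])) for name in names]
    n_gaps = {}
    for name in names:
        gaps = _n_runs(str(fa[name][:]), min_gap)
        if gaps:
            n_gaps[name] = gaps
    centromeres = None
    if centromere_bed is not None:
        bed = read_bed(centromere_bed)
        centromeres = {
            row.chrom: int((row.start + row.end) // 2) for row in bed.itertuples()
        }
    return ReferenceIndex(chromosomes=chromosomes, n_gaps=n_gaps, centromeres=centromeres)


# ---------------------------------------------------------------------------
# VCF

_ANNOT_KEYS = ("QD", "FS", "MQ")


def read_vcf(vcf_path: str | os.PathLike) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a single-sample VCF.

    Multi-allelic sites are split into one record per alternate allele, the
    per-allele AD paired with AD[0] for the reference.  Missing QD/FS/MQ are
    recorded in ``VariantRecord.missing`` instead of being defaulted.
    """
    with pysam.VariantFile(str(vcf_path)) as vf:
        n_samples = len(vf.header.samples)
        if n_samples != 1:
            raise ValueError(
                f"{vcf_path}: expected a single-sample VCF, found {n_samples} samples"
            )
        for i, rec in enumerate(vf.fetch() if vf.index else vf):
            try:
                yield from _split_record(rec)
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(
                    f"{vcf_path}: malformed record #{i + 1} at "
                    f"{rec.chrom}:{rec.pos}: {exc}"
                ) from exc


def _split_record(rec: "pysam.VariantRecord") -> Iterator[VariantRecord]:
    if rec.alts is None:
        return
    missing = tuple(k for k in _ANNOT_KEYS if k not in rec.info)
    annot = {k: float(rec.info[k]) if k in rec.info else float("nan") for k in _ANNOT_KEYS}
    sample = rec.samples[0]
    ad = sample.get("AD")
    dp = sample.get("DP")
    if ad is None or ad[0] is None:
        raise ValueError("missing FORMAT/AD")
    if dp is None:
        dp = sum(a for a in ad if a is not None)
    for alt_idx, alt in enumerate(rec.alts, start=1):
        ad_alt = ad[alt_idx] if alt_idx < len(ad) and ad[alt_idx] is not None else 0
        yield VariantRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref_allele=rec.ref,
            alt_allele=alt,
            qd=annot["QD"],
            fs=annot["FS"],
            mq=annot["MQ"],
            ad_ref=int(ad[0]),
            ad_alt=int(ad_alt),
            dp=int(dp),
            missing=missing,
        )


def _vcf_header(ref: ReferenceIndex, sample: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in ref.chromosomes:
        header.contigs.add(name, length=length)
    header.info.add("QD", 1, "Float", "Variant quality by depth")
    header.info.add("FS", 1, "Float", "Phred-scaled Fisher strand bias")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.add_sample(sample)
    return header


def write_vcf(
    records: Iterable[VariantRecord],
    ref: ReferenceIndex,
    path: str | os.PathLike,
    sample: str = "sample1",
) -> None:
    """Write biallelic VariantRecords to an uncompressed VCF."""
    header = _vcf_header(ref, sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            rec = out.new_record(
                contig=r.chrom,
                start=r.pos - 1,
                alleles=(r.ref_allele, r.alt_allele),
            )
            for key, val in (("QD", r.qd), ("FS", r.fs), ("MQ", r.mq)):
                if key not in r.missing and not np.isnan(val):
                    rec.info[key] = val
            rec.samples[sample]["GT"] = (0, 1)
            rec.samples[sample]["AD"] = (r.ad_ref, r.ad_alt)
            rec.samples[sample]["DP"] = r.dp
            out.write(rec)


# ---------------------------------------------------------------------------
# Depth tables


def read_depth(path: str | os.PathLike) -> DepthTrack:
    """Read a depth table.

    Accepts samtools-depth-like 3-column TSV (chrom, pos, depth; no header,
    1-based positions) or a pre-binned 4-column TSV (chrom, start, end,
    mean_depth; 0-based half-open, header optional).
    """
    first = pd.read_csv(path, sep="\t", nrows=1, header=None, dtype=str)
    ncol = first.shape[1]
    has_header = not str(first.iloc[0, 1]).lstrip("-").isdigit()
    skip = 1 if has_header else 0
    if ncol == 3:
        frame = pd.read_csv(
            path, sep="\t", header=None, skiprows=skip,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
        )
        return DepthTrack(frame=frame, kind="per_position")
    if ncol == 4:
        frame = pd.read_csv(
            path, sep="\t", header=None, skiprows=skip,
            names=["chrom", "start", "end", "mean_depth"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "mean_depth": float},
        )
        return DepthTrack(frame=frame, kind="binned")
    raise ValueError(f"{path}: expected 3 or 4 depth columns, found {ncol}")


# ---------------------------------------------------------------------------
# BED / TSV


def write_bed(
    intervals: Iterable[Sequence], path: str | os.PathLike
) -> None:
    """Write (chrom, start, end[, name...]) rows as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end, *rest = row
            fields = [str(chrom), str(int(start)), str(int(end))]
            fields.extend(str(x) for x in rest)
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED into a DataFrame with chrom/start/end (+name if present)."""
    try:
        frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    names = ["chrom", "start", "end", "name", "score", "strand"]
    frame.columns = names[: frame.shape[1]]
    frame["chrom"] = frame["chrom"].astype(str)
    return frame


def write_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a DataFrame as TSV with a header row (round-trips via read_tsv)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
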