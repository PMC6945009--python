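"""Genome-wide variant landscape: density tracks, the CDS InDel mod-3 length
bias, and a minimal high-impact effect classifier.

The effect classifier covers the three disruptive classes usually reported
from resequencing screens — premature stop codons (stop_gained), destroyed
terminal stops (stop_lost) and frameshifts — plus "other" for everything
else.  It works at codon resolution: a variant is mapped into the spliced
coding sequence (minus-strand genes via the reverse complement) and only the
affected codons are re-evaluated against the standard genetic code.
Precedence when several classes apply: frameshift > stop_gained > stop_lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree
from scipy.stats import chi2_contingency, fisher_exact

from .core_io import ReferenceIndex, VariantRecord

__all__ = [
    "GeneModel",
    "EffectCall",
    "Mod3Result",
    "read_gff3",
    "density_track",
    "indel_mod3_bias",
    "two_proportion_test",
    "classify_effect",
    "classify_effects",
    "spliced_cds",
]

logger = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneModel:
    """One gene's coding structure: sorted, non-overlapping CDS intervals
    (0-based half-open, genomic) with per-interval phase."""

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    cds_intervals: list[tuple[int, int]]
    phases: list[int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = -1
        for s, e in self.cds_intervals:
            if s >= e or s < prev_end:
                raise ValueError(f"bad/overlapping CDS intervals in {self.gene_id}")
            prev_end = e

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def complete(self) -> bool:
        return self.cds_length % 3 == 0


@dataclass
class EffectCall:
    chrom: str
    pos: int
    effect: str  # stop_gained | stop_lost | frameshift | other
    gene_id: str | None


@dataclass
class Mod3Result:
    """Fractions of mod-3 InDel lengths inside vs outside CDS and a
    two-proportion comparison of them."""

    p_cds: float | None
    p_noncds: float | None
    n_cds: int
    n_noncds: int
    diff: float | None
    p_value: float | None
    method: str


def read_gff3(path) -> list[GeneModel]:
    """Gene models (CDS features grouped by parent) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_parent: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parent = cds.attributes.get("Parent", [cds.id or "unknown"])[0]
        by_parent.setdefault(parent, []).append(cds)
    genes = []
    for parent, features in sorted(by_parent.items()):
        features.sort(key=lambda f: f.start)
        genes.append(
            GeneModel(
                gene_id=parent,
                chrom=features[0].seqid,
                strand=features[0].strand,
                cds_intervals=[(f.start - 1, f.end) for f in features],
                phases=[int(f.frame) if f.frame != "." else 0 for f in features],
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Density track


def density_track(
    variants: Iterable[VariantRecord],
    ref: ReferenceIndex,
    window: int = 100_000,
) -> pd.DataFrame:
    """SNV and InDel counts per fixed-width window (two separate columns,
    mirroring the two axes of a variant-density plot)."""
    lengths = ref.lengths
    counts: dict[tuple[str, int], list[int]] = {}
    for rec in variants:
        if rec.chrom not in lengths:
            raise ValueError(f"variant chromosome {rec.chrom!r} not in reference")
        pos0 = rec.pos - 1
        if pos0 >= lengths[rec.chrom] or pos0 < 0:
            raise ValueError(
                f"variant at {rec.chrom}:{rec.pos} beyond chromosome end"
            )
        key = (rec.chrom, pos0 // window)
        cell = counts.setdefault(key, [0, 0])
        cell[0 if rec.vtype == "SNV" else 1] += 1
    rows = []
    for chrom, length in ref.chromosomes:
        for w in range(0, (length + window - 1) // window):
            snv, indel = counts.get((chrom, w), (0, 0))
            rows.append(
                (chrom, w * window, min((w + 1) * window, length), snv, indel)
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "snv_count", "indel_count"]
    )


# ---------------------------------------------------------------------------
# InDel mod-3 bias


def _cds_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault(g.chrom, IntervalTree())
        for s, e in g.cds_intervals:
            tree[s:e] = g.gene_id
    return trees


def indel_affected_interval(rec: VariantRecord) -> tuple[int, int]:
    """Genomic bp affected by an InDel, 0-based half-open.

    Deletions cover the deleted bases; insertions are taken as the single
    anchor base they attach to.
    """
    if len(rec.ref_allele) > len(rec.alt_allele):  # deletion
        return rec.pos, rec.pos - 1 + len(rec.ref_allele)
    return rec.pos - 1, rec.pos


def indel_mod3_bias(
    indels: Iterable[VariantRecord],
    genes: Sequence[GeneModel],
) -> Mod3Result:
    """Fraction of InDel lengths divisible by 3 inside vs outside CDS.

    "Inside" means the affected interval overlaps any CDS interval.  The
    comparison is a two-sided two-proportion test: chi-square with Yates
    continuity correction, or Fisher's exact test when any cell is < 10.
    """
    trees = _cds_trees(genes)
    n = {"cds": 0, "noncds": 0}
    mod3 = {"cds": 0, "noncds": 0}
    for rec in indels:
        if rec.vtype != "InDel" or rec.indel_length == 0:
            continue
        s, e = indel_affected_interval(rec)
        tree = trees.get(rec.chrom)
        cls = "cds" if tree is not None and tree.overlap(s, e) else "noncds"
        n[cls] += 1
        if rec.indel_length % 3 == 0:
            mod3[cls] += 1
    p_cds = mod3["cds"] / n["cds"] if n["cds"] else None
    p_noncds = mod3["noncds"] / n["noncds"] if n["noncds"] else None
    if p_cds is None or p_noncds is None:
        return Mod3Result(p_cds, p_noncds, n["cds"], n["noncds"], None, None, "skipped")
    p_value, method = two_proportion_test(
        mod3["cds"], n["cds"], mod3["noncds"], n["noncds"]
    )
    return Mod3Result(
        p_cds=p_cds,
        p_noncds=p_noncds,
        n_cds=n["cds"],
        n_noncds=n["noncds"],
        diff=p_cds - p_noncds,
        p_value=p_value,
        method=method,
    )


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, str]:
    """Two-sided comparison of proportions k1/n1 vs k2/n2.

    Chi-square with Yates continuity correction (equivalent to the
    continuity-corrected two-proportion z test), falling back to Fisher's
    exact test when any contingency cell is below 10.
    """
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if (table < 10).any():
        _, p_value = fisher_exact(table, alternative="two-sided")
        return float(p_value), "fisher-exact"
    _, p_value, _, _ = chi2_contingency(table, correction=True)
    return float(p_value), "two-proportion-z-cc"


# ---------------------------------------------------------------------------
# Effect classification


def spliced_cds(gene: GeneModel, ref_seqs) -> str:
    """Coding sequence of ``gene``, 5'->3' (minus strand reverse-complemented).

    ``ref_seqs`` maps chromosome name to its sequence (str or anything
    sliceable returning str, e.g. a pyfaidx record).
    """
    chrom_seq = ref_seqs[gene.chrom]
    parts = [str(chrom_seq[s:e]) for s, e in gene.cds_intervals]
    cds = "".join(parts).upper()
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def _cds_offset(gene: GeneModel, pos0: int) -> int | None:
    """Offset of genomic position ``pos0`` in the 5'->3' CDS, or None."""
    offset = 0
    plus_offset = None
    for s, e in gene.cds_intervals:
        if s <= pos0 < e:
            plus_offset = offset + (pos0 - s)
            break
        offset += e - s
    if plus_offset is None:
        return None
    if gene.strand == "-":
        return gene.cds_length - 1 - plus_offset
    return plus_offset


def _overlap_len(gene: GeneModel, start: int, end: int) -> int:
    return sum(
        max(0, min(end, e) - max(start, s)) for s, e in gene.cds_intervals
    )


def classify_effect(
    variant: VariantRecord,
    gene: GeneModel | None,
    ref_seqs,
    boundary_mode: str = "overlap",
) -> EffectCall:
    """Classify one variant against one gene model.

    SNVs: the affected codon is re-read; a new in-frame stop before the
    terminal codon is stop_gained, a destroyed terminal stop is stop_lost.
    InDels: an in-CDS length change not divisible by 3 is a frameshift
    (``boundary_mode="overlap"`` counts only the portion inside CDS for
    boundary-spanning InDels; ``"whole"`` uses the full length); in-frame
    InDels are re-scanned over the affected codons for created or destroyed
    stops.  Anything outside CDS is "other" with gene None.
    """
    if gene is None:
        return EffectCall(variant.chrom, variant.pos, "other", None)
    pos0 = variant.pos - 1
    if not gene.complete:
        logger.warning(
            "gene %s: CDS length %d not divisible by 3; classifying on the "
            "available frame", gene.gene_id, gene.cds_length,
        )
    if variant.vtype == "InDel":
        return _classify_indel(variant, gene, ref_seqs, boundary_mode)
    offset = _cds_offset(gene, pos0)
    if offset is None:
        return EffectCall(variant.chrom, variant.pos, "other", None)
    cds = spliced_cds(gene, ref_seqs)
    alt_base = variant.alt_allele.upper()
    if gene.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    mutated = cds[:offset] + alt_base + cds[offset + 1:]
    codon_idx = offset // 3
    last_codon = len(cds) // 3 - 1
    old = cds[codon_idx * 3: codon_idx * 3 + 3]
    new = mutated[codon_idx * 3: codon_idx * 3 + 3]
    if len(new) == 3 and new in STOP_CODONS and old not in STOP_CODONS and codon_idx < last_codon:
        effect = "stop_gained"
    elif len(old) == 3 and old in STOP_CODONS and new not in STOP_CODONS:
        effect = "stop_lost"
    else:
        effect = "other"
    return EffectCall(variant.chrom, variant.pos, effect, gene.gene_id)


def _classify_indel(
    variant: VariantRecord,
    gene: GeneModel,
    ref_seqs,
    boundary_mode: str,
) -> EffectCall:
    pos0 = variant.pos - 1
    is_del = len(variant.ref_allele) > len(variant.alt_allele)
    if is_del:
        del_start, del_end = pos0 + 1, pos0 + len(variant.ref_allele)
        in_cds = _overlap_len(gene, del_start, del_end)
        if in_cds == 0:
            return EffectCall(variant.chrom, variant.pos, "other", None)
        cds_change = in_cds if boundary_mode == "overlap" else variant.indel_length
    else:
        anchor_in = _cds_offset(gene, pos0)
        next_in = _cds_offset(gene, pos0 + 1)
        if anchor_in is None and next_in is None:
            return EffectCall(variant.chrom, variant.pos, "other", None)
        cds_change = variant.indel_length
    if cds_change % 3 != 0:
        return EffectCall(variant.chrom, variant.pos, "frameshift", gene.gene_id)
    # in-frame: rebuild the CDS with the variant applied and re-scan the
    # affected codon window for created/destroyed stops
    cds = spliced_cds(gene, ref_seqs)
    applied = _apply_to_cds(variant, gene, cds)
    if applied is None:
        # affected bases only partially inside CDS but frame preserved
        return EffectCall(variant.chrom, variant.pos, "other", gene.gene_id)
    mutated, first_changed = applied
    n_changed = max(len(variant.ref_allele), len(variant.alt_allele))
    lo = (first_changed // 3) * 3
    hi = min(len(mutated), ((first_changed + n_changed) // 3 + 1) * 3)
    last_codon_start = len(cds) - 3
    new_window = [mutated[i:i + 3] for i in range(lo, hi, 3)]
    premature = any(
        c in STOP_CODONS and (lo + 3 * j) < len(mutated) - 3
        for j, c in enumerate(new_window)
        if len(c) == 3
    )
    terminal_new = mutated[-3:] if len(mutated) >= 3 else ""
    terminal_old = cds[last_codon_start:last_codon_start + 3]
    if premature:
        effect = "stop_gained"
    elif terminal_old in STOP_CODONS and terminal_new not in STOP_CODONS:
        effect = "stop_lost"
    else:
        effect = "other"
    return EffectCall(variant.chrom, variant.pos, effect, gene.gene_id)


def _apply_to_cds(
    variant: VariantRecord, gene: GeneModel, cds: str
) -> tuple[str, int] | None:
    """Apply an InDel fully contained in one CDS interval to the spliced CDS.

    Returns (mutated cds, first changed offset) or None when the affected
    bases are not fully inside the CDS (boundary-spanning case).
    """
    pos0 = variant.pos - 1
    ref_len = len(variant.ref_allele)
    interval = None
    for s, e in gene.cds_intervals:
        if s <= pos0 and pos0 + ref_len <= e:
            interval = (s, e)
            break
    if interval is None:
        return None
    offset_plus = 0
    for s, e in gene.cds_intervals:
        if (s, e) == interval:
            offset_plus += pos0 - s
            break
        offset_plus += e - s
    ref_a = variant.ref_allele.upper()
    alt_a = variant.alt_allele.upper()
    if gene.strand == "+":
        offset = offset_plus
        mutated = cds[:offset] + alt_a + cds[offset + ref_len:]
        return mutated, offset
    # minus strand: the allele block maps to the reverse complement
    end_plus = offset_plus + ref_len
    offset = gene.cds_length - end_plus
    ref_rc = str(Seq(ref_a).reverse_complement())
    alt_rc = str(Seq(alt_a).reverse_complement())
    assert cds[offset:offset + ref_len] == ref_rc, "reference allele mismatch"
    mutated = cds[:offset] + alt_rc + cds[offset + ref_len:]
    return mutated, offset


def classify_effects(
    variants: Iterable[VariantRecord],
    genes: Sequence[GeneModel],
    ref_seqs,
    boundary_mode: str = "overlap",
) -> list[EffectCall]:
    """Classify every variant against the gene (if any) whose CDS it overlaps."""
    trees = _cds_trees(genes)
    gene_by_id = {g.gene_id: g for g in genes}
    calls = []
    for rec in variants:
        tree = trees.get(rec.chrom)
        gene = None
        if tree is not None:
            if rec.vtype == "InDel":
                s, e = indel_affected_interval(rec)
            else:
                s, e = rec.pos - 1, rec.pos
            hits = tree.overlap(s, e)
            if hits:
                gene = gene_by_id[min(h.data for h in hits)]
        calls.append(classify_effect(rec, gene, ref_seqs, boundary_mode))
    return calls
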