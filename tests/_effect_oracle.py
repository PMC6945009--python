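"""Independent oracle for effect classification: apply the variant to the
chromosome, re-extract the spliced CDS with shifted coordinates, translate
both proteins with Biopython and diff them.  Shares no codon logic with the
classifier under test."""

from Bio.Seq import Seq

from ploidyscan.core_io import VariantRecord
from ploidyscan.landscape import GeneModel, spliced_cds


def oracle_effect(variant: VariantRecord, gene: GeneModel, chrom_seq: str) -> str:
    pos0 = variant.pos - 1
    ref_a, alt_a = variant.ref_allele.upper(), variant.alt_allele.upper()
    assert chrom_seq[pos0: pos0 + len(ref_a)].upper() == ref_a
    mut_chrom = chrom_seq[:pos0] + alt_a + chrom_seq[pos0 + len(ref_a):]
    delta = len(alt_a) - len(ref_a)
    new_ivs = []
    for s, e in gene.cds_intervals:
        if e <= pos0:
            new_ivs.append((s, e))
        elif s <= pos0:
            new_ivs.append((s, e + delta))
        else:
            new_ivs.append((s + delta, e + delta))
    mut_gene = GeneModel(gene.gene_id, gene.chrom, gene.strand, new_ivs)
    ref_cds = spliced_cds(gene, {gene.chrom: chrom_seq})
    mut_cds = spliced_cds(mut_gene, {gene.chrom: mut_chrom})
    if len(mut_cds) % 3 != 0:
        return "frameshift"
    ref_p = str(Seq(ref_cds).translate())
    mut_p = str(Seq(mut_cds).translate())
    premature = "*" in mut_p[:-1]
    if premature and "*" not in ref_p[:-1]:
        return "stop_gained"
    if ref_p.endswith("*") and not mut_p.endswith("*") and not premature:
        return "stop_lost"
    return "other"


def random_cds_variants(rng, genes, seqs, n):
    """Random SNVs and short InDels fully inside single CDS intervals."""
    variants = []
    gene_list = [g for g in genes if g.cds_intervals]
    while len(variants) < n:
        gene = gene_list[int(rng.integers(0, len(gene_list)))]
        s, e = gene.cds_intervals[int(rng.integers(0, len(gene.cds_intervals)))]
        kind = rng.random()
        chrom_seq = seqs[gene.chrom]
        if kind < 0.6:  # SNV
            pos0 = int(rng.integers(s, e))
            ref_a = chrom_seq[pos0]
            alt_a = "ACGT".replace(ref_a, "")[int(rng.integers(0, 3))]
        elif kind < 0.8:  # insertion after anchor, anchor not last interval base
            if e - s < 2:
                continue
            pos0 = int(rng.integers(s, e - 1))
            ref_a = chrom_seq[pos0]
            ilen = int(rng.integers(1, 7))
            alt_a = ref_a + "".join(
                "ACGT"[i] for i in rng.integers(0, 4, size=ilen)
            )
        else:  # deletion fully inside the interval
            dlen = int(rng.integers(1, 7))
            if e - s < dlen + 2:
                continue
            pos0 = int(rng.integers(s, e - dlen - 1))
            ref_a = chrom_seq[pos0: pos0 + dlen + 1]
            alt_a = ref_a[0]
        if "N" in ref_a:
            continue
        variants.append(
            (VariantRecord(gene.chrom, pos0 + 1, ref_a, alt_a, 30, 1, 60, 30, 30, 60),
             gene)
        )
    return variants
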