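"""Variant-density tracks, InDel mod-3 bias, effect classification."""

import numpy as np
import pytest
from Bio.Seq import Seq
from pyfaidx import Fasta

from _effect_oracle import oracle_effect, random_cds_variants
from ploidyscan.core_io import ReferenceIndex, VariantRecord
from ploidyscan.landscape import (
    GeneModel,
    classify_effect,
    classify_effects,
    density_track,
    indel_mod3_bias,
    read_gff3,
    two_proportion_test,
)
from ploidyscan.simulate import sample_indel_lengths


def snv_at(chrom, pos, ref="A", alt="G"):
    return VariantRecord(chrom, pos, ref, alt, 30, 1, 60, 20, 20, 40)


def indel_at(chrom, pos, length, kind="ins"):
    if kind == "ins":
        return VariantRecord(chrom, pos, "A", "A" + "T" * length, 30, 1, 60, 20, 20, 40)
    return VariantRecord(chrom, pos, "A" + "T" * length, "A", 30, 1, 60, 20, 20, 40)


class TestDensityTrack:
    def test_window_counting(self):
        ref = ReferenceIndex([("c1", 200_000)])
        variants = [snv_at("c1", 10), snv_at("c1", 50_000), snv_at("c1", 99_999)]
        track = density_track(variants, ref)
        assert track["snv_count"].tolist() == [3, 0]

    def test_boundary_position(self):
        # 1-based pos 100000 -> 0-based 99999 -> still the first window
        ref = ReferenceIndex([("c1", 200_000)])
        track = density_track([snv_at("c1", 100_000), snv_at("c1", 100_001)], ref)
        assert track["snv_count"].tolist() == [1, 1]

    def test_conservation_and_separate_indel_axis(self, rng):
        ref = ReferenceIndex([("c1", 500_000), ("c2", 300_000)])
        variants = [
            snv_at("c1", int(p)) for p in rng.integers(1, 500_001, 200)
        ] + [indel_at("c2", int(p), 2) for p in rng.integers(1, 300_000, 50)]
        track = density_track(variants, ref)
        assert track["snv_count"].sum() == 200
        assert track["indel_count"].sum() == 50

    def test_beyond_chromosome_end_rejected(self):
        ref = ReferenceIndex([("c1", 1000)])
        with pytest.raises(ValueError, match="beyond chromosome end"):
            density_track([snv_at("c1", 1001)], ref)


class TestMod3Bias:
    def test_counting_example(self):
        genes = [GeneModel("g1", "c1", "+", [(1000, 2000)])]
        cds = [indel_at("c1", 1500 + i, ln) for i, ln in enumerate([3, 6, 3, 1])]
        noncds = [indel_at("c1", 5000 + 10 * i, ln)
                  for i, ln in enumerate([1, 2, 3, 4, 5, 6])]
        res = indel_mod3_bias(cds + noncds, genes)
        assert res.p_cds == pytest.approx(0.75)
        assert res.p_noncds == pytest.approx(1 / 3)
        assert res.diff == pytest.approx(0.75 - 1 / 3)

    def test_empty_class_skipped(self):
        genes = [GeneModel("g1", "c1", "+", [(1000, 2000)])]
        res = indel_mod3_bias([indel_at("c1", 5000, 3)], genes)
        assert res.method == "skipped" and res.p_cds is None

    def test_enriched_lengths_give_positive_diff(self, rng):
        genes = [GeneModel("g1", "c1", "+", [(0, 10_000)])]
        cds_lens = sample_indel_lengths(rng, 200, mod3_enrichment=3.0)
        non_lens = sample_indel_lengths(rng, 800, mod3_enrichment=1.0)
        indels = [indel_at("c1", 10 + i, int(l)) for i, l in enumerate(cds_lens)]
        indels += [indel_at("c1", 20_000 + 40 * i, int(l))
                   for i, l in enumerate(non_lens)]
        res = indel_mod3_bias(indels, genes)
        assert res.diff > 0 and res.p_value < 0.01

    def test_null_lengths_give_small_diff(self, rng):
        """Identical length distributions: |p_cds - p_noncds| within 3 sd of
        the two-sample sampling noise."""
        genes = [GeneModel("g1", "c1", "+", [(0, 30_000)])]
        n1, n2 = 400, 1600
        l1 = sample_indel_lengths(rng, n1)
        l2 = sample_indel_lengths(rng, n2)
        indels = [indel_at("c1", 10 + 60 * i, int(l)) for i, l in enumerate(l1)]
        indels += [indel_at("c1", 50_000 + 40 * i, int(l))
                   for i, l in enumerate(l2)]
        res = indel_mod3_bias(indels, genes)
        p_hat = (res.p_cds * n1 + res.p_noncds * n2) / (n1 + n2)
        sd = np.sqrt(p_hat * (1 - p_hat) * (1 / n1 + 1 / n2))
        assert abs(res.diff) < 3 * sd


# ---------------------------------------------------------------------------
# effect classification

# A complete little ORF: ATG + codons + TAA.  "TAC" at codon 4 can become TAA.
ORF = "ATG" + "GCT" + "CCG" + "TAC" + "GGA" + "TTC" + "TAA"


def plus_gene(offset=100):
    return GeneModel("g+", "c1", "+", [(offset, offset + len(ORF))])


def make_seqs(offset=100, pad=400):
    seq = "A" * offset + ORF + "C" * pad
    return {"c1": seq}


class TestClassifyEffect:
    def test_frameshift_two_bp_insertion(self):
        seqs = make_seqs()
        var = indel_at("c1", 105, 2)  # inside CDS, 2 % 3 != 0
        var = VariantRecord("c1", 105, seqs["c1"][104], seqs["c1"][104] + "TT",
                            30, 1, 60, 20, 20, 40)
        call = classify_effect(var, plus_gene(), seqs)
        assert call.effect == "frameshift"

    def test_inframe_deletion_is_other(self):
        seqs = make_seqs()
        pos0 = 103  # deletes bases 104..106 (one full codon, no stop created)
        var = VariantRecord("c1", pos0 + 1, seqs["c1"][pos0: pos0 + 4],
                            seqs["c1"][pos0], 30, 1, 60, 20, 20, 40)
        call = classify_effect(var, plus_gene(), seqs)
        assert call.effect == "other"

    def test_stop_gained_tac_to_taa(self):
        seqs = make_seqs()
        # codon 4 (TAC) starts at CDS offset 9 -> genomic pos0 109, C at 111
        var = VariantRecord("c1", 112, "C", "A", 30, 1, 60, 20, 20, 40)
        call = classify_effect(var, plus_gene(), seqs)
        assert call.effect == "stop_gained"

    def test_stop_lost_snv_in_terminal_codon(self):
        seqs = make_seqs()
        # terminal TAA starts at CDS offset 18 -> pos0 118; TAA->TAC loses stop
        var = VariantRecord("c1", 121, "A", "C", 30, 1, 60, 20, 20, 40)
        call = classify_effect(var, plus_gene(), seqs)
        assert call.effect == "stop_lost"

    def test_outside_cds_is_other_without_gene(self):
        seqs = make_seqs()
        call = classify_effect(snv_at("c1", 10), plus_gene(), seqs)
        assert call.effect == "other" and call.gene_id is None

    def test_strand_symmetry(self):
        """A gene and its reverse-complement mirror classify identically."""
        seqs = make_seqs()
        fwd = plus_gene()
        L = len(seqs["c1"])
        rc_seq = str(Seq(seqs["c1"]).reverse_complement())
        rev = GeneModel("g-", "c1", "-", [(L - 100 - len(ORF), L - 100)])
        rc_seqs = {"c1": rc_seq}
        cases = [
            VariantRecord("c1", 112, "C", "A", 30, 1, 60, 20, 20, 40),  # stop gained
            VariantRecord("c1", 121, "A", "C", 30, 1, 60, 20, 20, 40),  # stop lost
            VariantRecord("c1", 105, seqs["c1"][104], seqs["c1"][104] + "TT",
                          30, 1, 60, 20, 20, 40),  # frameshift
        ]
        for var in cases:
            fwd_call = classify_effect(var, fwd, seqs)
            # mirror the variant into the reverse-complemented coordinate frame
            pos0 = var.pos - 1
            ref_rc = str(Seq(var.ref_allele).reverse_complement())
            alt_rc = str(Seq(var.alt_allele).reverse_complement())
            mpos0 = L - pos0 - len(var.ref_allele)
            mirrored = VariantRecord("c1", mpos0 + 1, ref_rc, alt_rc,
                                     30, 1, 60, 20, 20, 40)
            rev_call = classify_effect(mirrored, rev, rc_seqs)
            assert rev_call.effect == fwd_call.effect


class TestOracleAgreement:
    def test_classifier_matches_translate_and_diff(self, small_sim, rng):
        cfg, out = small_sim
        genes = read_gff3(out.gff3)
        fasta = Fasta(str(out.fasta))
        seqs = {name: str(fasta[name][:]) for name in fasta.keys()}
        disagreements = []
        for var, gene in random_cds_variants(rng, genes, seqs, 400):
            got = classify_effect(var, gene, seqs).effect
            want = oracle_effect(var, gene, seqs[gene.chrom])
            if got != want:
                disagreements.append((var, got, want))
        assert disagreements == []

    def test_classify_effects_assigns_genes(self, small_sim):
        cfg, out = small_sim
        genes = read_gff3(out.gff3)
        fasta = Fasta(str(out.fasta))
        g = genes[0]
        pos0 = g.cds_intervals[0][0] + 1
        base = str(fasta[g.chrom][pos0])
        alt = "ACGT".replace(base, "")[0]
        var = VariantRecord(g.chrom, pos0 + 1, base, alt, 30, 1, 60, 20, 20, 40)
        calls = classify_effects([var], genes, fasta)
        assert calls[0].gene_id == g.gene_id


def test_gff3_round_trip_structure(small_sim):
    cfg, out = small_sim
    genes = read_gff3(out.gff3)
    assert len(genes) == out.truth["n_genes"]
    for g in genes[:20]:
        assert g.complete, f"{g.gene_id} CDS length {g.cds_length} not mod 3"


def test_two_proportion_test_methods():
    p_big, m_big = two_proportion_test(60, 200, 30, 200)
    assert m_big == "two-proportion-z-cc" and p_big < 0.01
    p_small, m_small = two_proportion_test(2, 12, 3, 14)
    assert m_small == "fisher-exact" and p_small > 0.5
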