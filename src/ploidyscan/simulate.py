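"""Synthetic reference + resequencing-sample generator with a truth set.

The generator realizes the generative model the downstream analyses assume
for a partially heterozygous polyploid: a k-ploid sample whose haplophases
split into reference-like copies (nearly identical to the assembly) and
divergent copies (carrying most heterozygous variation), one optional
segmental duplication adding an extra copy of one class, depth proportional
to local copy number, and binomial sampling of reads across haplophases.
Reads themselves are never simulated: the pipeline starts at a VCF plus a
depth table, so depths and allelic depths are drawn directly from the model.

Heterozygous SNV sites come in four classes (per-bp rates):

* divergent-only   — alt on every divergent copy; AF_ref = r/(r + m*d)
* shared           — alt on the divergent copies plus ONE reference-like
                     copy (the "vice versa" sites producing the lower AF
                     peak); AF_ref = (r-1)/(r-1+1+m*d)
* ref-like-only    — alt on one reference-like copy
* reference-mismatch — every sample copy carries alt (the assembly deviates
                     from an invariant sample position); AF_ref ~ 0, excluded
                     by the spectrum's invariant cutoff

where r = reference-like copies, d = divergent copies and m the divergent
mapping rate (divergent reads map at a slightly reduced rate, thinning both
depth and allele-depth contributions).

Defaults model a triploid (2 reference-like + 1 divergent) over 3 x 2 Mbp
chromosomes with one 600 kb duplication of a reference-like haplophase — a
linear scale-down of a megabase-scale chromosome-arm event that keeps at
least six 100 kb windows inside the duplication — plus window-aligned N-gap
stretches and CDS-aware InDel length biases.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core_io import ReferenceIndex, VariantRecord, write_bed, write_vcf

__all__ = ["SimConfig", "SimOutput", "simulate", "sample_indel_lengths"]

BASES = np.frombuffer(b"ACGT", dtype="S1")
STOPS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOPS
]


@dataclass
class SimConfig:
    """Parameters of the synthetic polyploid resequencing scenario."""

    seed: int = 0
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr01", 2_000_000), ("chr02", 2_000_000),
                                 ("chr03", 2_000_000)]
    )
    baseline_ploidy: int = 3
    n_ref_like: int = 2
    divergent_snv_rate: float = 0.005
    shared_snv_rate: float = 0.002
    ref_like_snv_rate: float = 0.0005
    ref_mismatch_rate: float = 0.001
    #: (chrom, start, end, extra_copy_source) or None
    duplication: tuple | None = ("chr02", 800_000, 1_400_000, "ref_like")
    depth_per_copy: float = 20.0
    depth_model: str = "poisson"  # "poisson" | "negative_binomial"
    nb_dispersion: float = 0.1
    divergent_map_rate: float = 0.9
    n_gap_intervals: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("chr01", 1_200_000, 1_300_000),
                                 ("chr03", 400_000, 600_000)]
    )
    n_genes: int = 300
    mean_cds_len: int = 1200
    indel_rate: float = 5e-4
    indel_max_len: int = 30
    cds_mod3_enrichment: float = 3.0
    fail_annotation_rate: float = 0.05
    sample: str = "sample1"

    def __post_init__(self) -> None:
        if isinstance(self.chromosomes, list):
            self.chromosomes = [tuple(c) for c in self.chromosomes]
        if self.duplication is not None:
            self.duplication = tuple(self.duplication)
        self.n_gap_intervals = [tuple(g) for g in self.n_gap_intervals]
        if not (1 <= self.n_ref_like < self.baseline_ploidy):
            raise ValueError("need 1 <= n_ref_like < baseline_ploidy")
        for name in ("divergent_snv_rate", "shared_snv_rate",
                     "ref_like_snv_rate", "ref_mismatch_rate", "indel_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 0.1:
                raise ValueError(f"{name}={rate} outside [0, 0.1]")
        if not 0 < self.divergent_map_rate <= 1:
            raise ValueError("divergent_map_rate must be in (0, 1]")
        lengths = dict(self.chromosomes)
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"zero-length chromosome {chrom}")
        if self.duplication is not None:
            chrom, start, end, source = self.duplication
            if chrom not in lengths or not 0 <= start < end <= lengths[chrom]:
                raise ValueError("duplication interval outside its chromosome")
            if source not in ("ref_like", "divergent"):
                raise ValueError(f"unknown duplication source {source!r}")
            for gc, gs, ge in self.n_gap_intervals:
                if gc == chrom and gs < end and start < ge:
                    raise ValueError(
                        "duplication overlaps an N-gap; truth would be undefined"
                    )
        for gc, gs, ge in self.n_gap_intervals:
            if gc not in lengths or not 0 <= gs < ge <= lengths[gc]:
                raise ValueError(f"N-gap [{gs},{ge}) outside chromosome {gc}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class SimOutput:
    """Paths of the generated files plus the in-memory truth set."""

    fasta: Path
    depth: Path
    vcf: Path
    gff3: Path
    truth_bed: Path
    truth_json: Path
    truth_sites: Path
    truth: dict
    ref_index: ReferenceIndex


def sample_indel_lengths(
    rng: np.random.Generator,
    n: int,
    max_len: int = 30,
    mod3_enrichment: float = 1.0,
    decay: float = 0.75,
) -> np.ndarray:
    """Draw InDel lengths 1..max_len with geometric-like decay; lengths
    divisible by 3 get their probability multiplied by ``mod3_enrichment``."""
    lengths = np.arange(1, max_len + 1)
    w = decay ** (lengths - 1)
    w = np.where(lengths % 3 == 0, w * mod3_enrichment, w)
    w = w / w.sum()
    return rng.choice(lengths, size=n, p=w)


def _class_weights(cfg: SimConfig, in_dup: bool) -> tuple[float, float, int, int]:
    """(ref_like_total_weight_per_copy_list..) helper: returns
    (n_ref_copies, n_div_copies) including the duplicated copy."""
    n_ref = cfg.n_ref_like
    n_div = cfg.baseline_ploidy - cfg.n_ref_like
    if in_dup and cfg.duplication is not None:
        if cfg.duplication[3] == "ref_like":
            n_ref += 1
        else:
            n_div += 1
    return n_ref, n_div


def _p_alt(cfg: SimConfig, site_class: str, in_dup: bool, carrier: int) -> float:
    """Expected alt-read fraction at a site, map-rate thinning included.

    ``carrier`` indexes which reference-like haplophase carries the alt for
    shared/ref-like classes; the duplication copies haplophase index 0 of its
    source class.
    """
    m = cfg.divergent_map_rate
    n_ref, n_div = _class_weights(cfg, in_dup)
    total = n_ref + m * n_div
    dup_ref = in_dup and cfg.duplication is not None and cfg.duplication[3] == "ref_like"
    dup_div = in_dup and cfg.duplication is not None and cfg.duplication[3] == "divergent"
    base_div = cfg.baseline_ploidy - cfg.n_ref_like
    if site_class in ("divergent", "indel"):
        alt = m * base_div + (m if dup_div else 0.0)
    elif site_class == "shared":
        alt = m * base_div + (m if dup_div else 0.0)
        alt += 1.0 + (1.0 if (dup_ref and carrier == 0) else 0.0)
    elif site_class == "ref_like":
        alt = 1.0 + (1.0 if (dup_ref and carrier == 0) else 0.0)
    elif site_class == "ref_mismatch":
        alt = total
    else:  # pragma: no cover
        raise ValueError(site_class)
    return alt / total


def _place_genes(cfg: SimConfig, rng: np.random.Generator,
                 occupied: dict[str, list[tuple[int, int]]]):
    """Choose non-overlapping gene loci (1-2 CDS exons) avoiding N-gaps."""
    lengths = dict(cfg.chromosomes)
    total_len = sum(lengths.values())
    genes = []
    for chrom, length in cfg.chromosomes:
        n_here = int(round(cfg.n_genes * length / total_len))
        taken = sorted(occupied.get(chrom, []))
        for gi in range(n_here):
            n_codons = max(
                10, int(rng.normal(cfg.mean_cds_len / 3, cfg.mean_cds_len / 12))
            )
            cds_len = 3 * n_codons
            two_exons = rng.random() < 0.5
            intron = int(rng.integers(80, 400)) if two_exons else 0
            span = cds_len + intron
            placed = None
            for _ in range(60):
                start = int(rng.integers(0, max(1, length - span)))
                if all(start + span <= s or start >= e for s, e in taken):
                    placed = start
                    break
            if placed is None:
                continue
            taken.append((placed, placed + span))
            taken.sort()
            strand = "+" if rng.random() < 0.5 else "-"
            if two_exons:
                cut = int(rng.integers(3, cds_len - 3))
                intervals = [
                    (placed, placed + cut),
                    (placed + cut + intron, placed + span),
                ]
            else:
                intervals = [(placed, placed + span)]
            genes.append(
                {
                    "gene_id": f"gene_{chrom}_{gi:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "intervals": intervals,
                    "n_codons": n_codons,
                }
            )
        occupied[chrom] = taken
    return genes


def _gene_cds_sequence(rng: np.random.Generator, n_codons: int) -> str:
    body_idx = rng.integers(0, len(NON_STOP_CODONS), size=n_codons - 2)
    body = "".join(NON_STOP_CODONS[i] for i in body_idx)
    stop = STOPS[int(rng.integers(0, 3))]
    return "ATG" + body + stop


def _write_gene(seq_arr: np.ndarray, gene: dict, cds: str) -> None:
    genomic = cds if gene["strand"] == "+" else str(Seq(cds).reverse_complement())
    offset = 0
    for s, e in gene["intervals"]:
        seg = genomic[offset: offset + (e - s)]
        seq_arr[s:e] = np.frombuffer(seg.encode(), dtype="S1")
        offset += e - s


def _gff3_lines(gene: dict) -> list[str]:
    chrom, strand = gene["chrom"], gene["strand"]
    gid = gene["gene_id"]
    start = gene["intervals"][0][0] + 1
    end = gene["intervals"][-1][1]
    lines = [
        f"{chrom}\tploidyscan_sim\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}",
        f"{chrom}\tploidyscan_sim\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
        f"ID={gid}.t1;Parent={gid}",
    ]
    # phase: bases to skip at feature start to reach a codon boundary, in
    # transcript order (genomic order reversed on the minus strand)
    intervals = gene["intervals"]
    tx_order = intervals if strand == "+" else intervals[::-1]
    phases = {}
    cum = 0
    for iv in tx_order:
        phases[iv] = (3 - cum % 3) % 3
        cum += iv[1] - iv[0]
    for i, (s, e) in enumerate(intervals):
        lines.append(
            f"{chrom}\tploidyscan_sim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t"
            f"{phases[(s, e)]}\tID={gid}.cds{i};Parent={gid}.t1"
        )
    return lines


def simulate(cfg: SimConfig, outdir: str | os.PathLike) -> SimOutput:
    """Generate reference FASTA, depth TSV, VCF, GFF3 and truth files.

    Deterministic: the same config (seed included) yields byte-identical
    outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    lengths = dict(cfg.chromosomes)
    gaps: dict[str, list[tuple[int, int]]] = {}
    for gc, gs, ge in cfg.n_gap_intervals:
        gaps.setdefault(gc, []).append((gs, ge))
    for v in gaps.values():
        v.sort()

    # --- reference sequences, genes written in, then N-gaps ---------------
    seqs: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chromosomes:
        seqs[chrom] = BASES[rng.integers(0, 4, size=length)].copy()
    occupied = {c: list(g) for c, g in gaps.items()}
    genes = _place_genes(cfg, rng, occupied)
    for gene in genes:
        cds = _gene_cds_sequence(rng, gene["n_codons"])
        _write_gene(seqs[gene["chrom"]], gene, cds)
    for chrom, ivs in gaps.items():
        for s, e in ivs:
            seqs[chrom][s:e] = b"N"

    cds_mask = {
        chrom: np.zeros(length, dtype=bool) for chrom, length in cfg.chromosomes
    }
    for gene in genes:
        for s, e in gene["intervals"]:
            cds_mask[gene["chrom"]][s:e] = True

    # --- variant site placement -------------------------------------------
    dup = cfg.duplication
    site_rows = []  # (chrom, pos0, class, carrier, vtype, length)
    taken_sites: dict[str, set] = {c: set() for c in lengths}
    class_rates = [
        ("divergent", cfg.divergent_snv_rate),
        ("shared", cfg.shared_snv_rate),
        ("ref_like", cfg.ref_like_snv_rate),
        ("ref_mismatch", cfg.ref_mismatch_rate),
    ]
    for chrom, length in cfg.chromosomes:
        gap_mask = np.zeros(length, dtype=bool)
        for s, e in gaps.get(chrom, []):
            gap_mask[s:e] = True
        for cls, rate in class_rates:
            if rate <= 0:
                continue
            hit = np.flatnonzero((rng.random(length) < rate) & ~gap_mask)
            for pos0 in hit.tolist():
                if pos0 in taken_sites[chrom]:
                    continue
                taken_sites[chrom].add(pos0)
                carrier = (
                    int(rng.integers(0, cfg.n_ref_like))
                    if cls in ("shared", "ref_like")
                    else 0
                )
                site_rows.append((chrom, pos0, cls, carrier, "SNV", 0))
        # InDels, CDS-aware mod-3 length bias
        if cfg.indel_rate > 0:
            hit = np.flatnonzero((rng.random(length) < cfg.indel_rate) & ~gap_mask)
            for pos0 in hit.tolist():
                if pos0 in taken_sites[chrom]:
                    continue
                in_cds = bool(cds_mask[chrom][pos0])
                enrich = cfg.cds_mod3_enrichment if in_cds else 1.0
                ilen = int(
                    sample_indel_lengths(rng, 1, cfg.indel_max_len, enrich)[0]
                )
                is_del = rng.random() < 0.5
                if is_del and (
                    pos0 + ilen + 1 > length
                    or gap_mask[pos0: pos0 + ilen + 1].any()
                ):
                    continue
                taken_sites[chrom].add(pos0)
                site_rows.append(
                    (chrom, pos0, "indel", 0, "del" if is_del else "ins", ilen)
                )

    # --- depth track -------------------------------------------------------
    m = cfg.divergent_map_rate
    depth_arrays: dict[str, np.ndarray] = {}
    for chrom, length in cfg.chromosomes:
        n_ref0, n_div0 = _class_weights(cfg, in_dup=False)
        w = np.full(length, n_ref0 + m * n_div0, dtype=float)
        if dup is not None and dup[0] == chrom:
            n_ref1, n_div1 = _class_weights(cfg, in_dup=True)
            w[dup[1]: dup[2]] = n_ref1 + m * n_div1
        mu = w * cfg.depth_per_copy
        if cfg.depth_model == "poisson":
            depth = rng.poisson(mu)
        elif cfg.depth_model == "negative_binomial":
            lam = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu)
            depth = rng.poisson(lam)
        else:
            raise ValueError(f"unknown depth_model {cfg.depth_model!r}")
        for s, e in gaps.get(chrom, []):
            depth[s:e] = 0
        depth_arrays[chrom] = depth.astype(np.int64)

    # --- VCF records -------------------------------------------------------
    site_rows.sort(key=lambda r: (r[0], r[1]))
    records: list[VariantRecord] = []
    truth_sites = []
    for chrom, pos0, cls, carrier, vkind, ilen in site_rows:
        in_dup = dup is not None and dup[0] == chrom and dup[1] <= pos0 < dup[2]
        p_alt = _p_alt(cfg, "indel" if cls == "indel" else cls, in_dup, carrier)
        dp = int(depth_arrays[chrom][pos0])
        ad_alt = int(rng.binomial(dp, p_alt)) if dp > 0 else 0
        ad_ref = dp - ad_alt
        ref_base = seqs[chrom][pos0].decode()
        if cls == "indel":
            if vkind == "del":
                deleted = seqs[chrom][pos0 + 1: pos0 + 1 + ilen].tobytes().decode()
                ref_allele, alt_allele = ref_base + deleted, ref_base
            else:
                ins = BASES[rng.integers(0, 4, size=ilen)].tobytes().decode()
                ref_allele, alt_allele = ref_base, ref_base + ins
        else:
            others = [b for b in "ACGT" if b != ref_base]
            alt_allele = others[int(rng.integers(0, 3))]
            ref_allele = ref_base
        qd = float(rng.uniform(10, 35))
        fs = float(rng.uniform(0, 10))
        mq = float(rng.uniform(55, 60))
        is_snv = cls != "indel"
        if rng.random() < cfg.fail_annotation_rate:
            which = int(rng.integers(0, 3 if is_snv else 2))
            if which == 0:
                qd = float(rng.uniform(0.1, 1.9))
            elif which == 1:
                hi = 60.0 if is_snv else 200.0
                fs = float(rng.uniform(hi + 5, hi + 100))
            else:
                mq = float(rng.uniform(20, 39))
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos0 + 1,
                ref_allele=ref_allele, alt_allele=alt_allele,
                qd=qd, fs=fs, mq=mq,
                ad_ref=ad_ref, ad_alt=ad_alt, dp=dp,
            )
        )
        truth_sites.append((chrom, pos0 + 1, cls, carrier, vkind, ilen, in_dup))

    # --- write everything --------------------------------------------------
    ref_index = ReferenceIndex(
        chromosomes=list(cfg.chromosomes),
        n_gaps={c: list(v) for c, v in gaps.items()},
    )
    fasta_path = outdir / "reference.fasta"
    seq_records = [
        SeqRecord(Seq(seqs[chrom].tobytes().decode()), id=chrom, description="")
        for chrom, _ in cfg.chromosomes
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")

    depth_path = outdir / "depth.tsv"
    with open(depth_path, "w") as fh:
        for chrom, _ in cfg.chromosomes:
            depth = depth_arrays[chrom]
            pos = np.flatnonzero(depth > 0) + 1  # samtools-depth style: 1-based, >0 only
            pd.DataFrame({"chrom": chrom, "pos": pos, "depth": depth[pos - 1]}).to_csv(
                fh, sep="\t", header=False, index=False
            )

    vcf_path = outdir / "calls.vcf"
    write_vcf(records, ref_index, vcf_path, sample=cfg.sample)

    gff_path = outdir / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write("\n".join(_gff3_lines(gene)) + "\n")

    truth_bed = outdir / "truth.bed"
    bed_rows = []
    if dup is not None:
        bed_rows.append((dup[0], dup[1], dup[2], f"duplication_{dup[3]}"))
    for chrom, ivs in gaps.items():
        for s, e in ivs:
            bed_rows.append((chrom, s, e, "n_gap"))
    write_bed(bed_rows, truth_bed)

    n_div_base = cfg.baseline_ploidy - cfg.n_ref_like
    ploidy_map = []
    for chrom, length in cfg.chromosomes:
        if dup is not None and dup[0] == chrom:
            extra_ref = 1 if dup[3] == "ref_like" else 0
            pieces = [
                (0, dup[1], cfg.baseline_ploidy, cfg.n_ref_like, n_div_base),
                (dup[1], dup[2], cfg.baseline_ploidy + 1,
                 cfg.n_ref_like + extra_ref, n_div_base + 1 - extra_ref),
                (dup[2], length, cfg.baseline_ploidy, cfg.n_ref_like, n_div_base),
            ]
        else:
            pieces = [(0, length, cfg.baseline_ploidy, cfg.n_ref_like, n_div_base)]
        for s, e, cn, nr, nd in pieces:
            if s < e:
                ploidy_map.append(
                    {"chrom": chrom, "start": s, "end": e, "copy_number": cn,
                     "n_ref_like": nr, "n_divergent": nd}
                )
    truth = {
        "config": asdict(cfg),
        "ploidy_map": ploidy_map,
        "duplication": list(dup) if dup is not None else None,
        "n_gaps": {c: [list(iv) for iv in v] for c, v in gaps.items()},
        "site_counts": {
            k: int(v)
            for k, v in pd.Series([r[2] for r in truth_sites])
            .value_counts().sort_index().items()
        },
        "n_genes": len(genes),
    }
    truth_json = outdir / "truth.json"
    with open(truth_json, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    truth_sites_path = outdir / "truth_sites.tsv"
    pd.DataFrame(
        truth_sites,
        columns=["chrom", "pos", "site_class", "carrier", "kind", "indel_len",
                 "in_duplication"],
    ).to_csv(truth_sites_path, sep="\t", index=False)

    return SimOutput(
        fasta=fasta_path, depth=depth_path, vcf=vcf_path, gff3=gff_path,
        truth_bed=truth_bed, truth_json=truth_json,
        truth_sites=truth_sites_path, truth=truth, ref_index=ref_index,
    )
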