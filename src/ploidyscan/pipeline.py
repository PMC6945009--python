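"""End-to-end orchestration: filter -> cnv -> ploidy -> landscape.

Each stage writes its table(s) to disk; ``run_all`` chains them and emits a
single JSON report with the filter counts, segment table, ploidy calls,
density summary, mod-3 bias estimate and effect-class counts, stamped with
the package version, a config hash and the seed.  Stage outputs already on
disk are reused unless ``force`` is set, so an interrupted run can resume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from pyfaidx import Fasta

from . import __version__
from .af_ploidy import segment_ploidy
from .core_io import (
    ReferenceIndex,
    read_depth,
    read_reference,
    read_vcf,
    write_bed,
    write_tsv,
    write_vcf,
)
from .coverage import (
    mask_artifacts,
    normalize,
    segment,
    segments_to_frame,
    window_depth,
)
from .landscape import (
    classify_effects,
    density_track,
    indel_mod3_bias,
    read_gff3,
)
from .variant_filter import FilterConfig, filter_variants

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, outputs and parameters of a full pipeline run."""

    vcf: str
    depth: str
    reference: str
    gff3: str
    outdir: str
    centromeres: str | None = None
    window: int = 100_000
    baseline_ploidy: int = 3
    min_gap: int = 100
    min_seg: int = 5
    c_max: int = 6
    low_ratio: float = 0.15
    n_min: float = 0.5
    min_sites: int = 200
    k_max: int = 6
    include_indels: bool = False
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if isinstance(self.filter, dict):
            self.filter = FilterConfig(**self.filter)
        for name in ("vcf", "depth", "reference", "gff3"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} input does not exist: {path}")
        if self.centromeres is not None and not Path(self.centromeres).exists():
            raise FileNotFoundError(
                f"centromeres input does not exist: {self.centromeres}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(
            {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
             for k, v in dataclasses.asdict(self).items()},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def run_all(cfg: PipelineConfig, force: bool = False, plots: bool = False) -> dict:
    """Run filter, CNV, ploidy and landscape stages and write a JSON report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = read_reference(cfg.reference, min_gap=cfg.min_gap,
                         centromere_bed=cfg.centromeres)

    # --- filter -----------------------------------------------------------
    stage = "filter"
    kept_vcf = outdir / "kept.vcf"
    filter_report_path = outdir / "filter_report.tsv"
    try:
        records = list(read_vcf(cfg.vcf))
        result = filter_variants(records, cfg.filter)
        kept = result.kept
        if force or not _stage_done([kept_vcf, filter_report_path]):
            write_vcf(kept, ref, kept_vcf)
            write_tsv(
                pd.DataFrame(
                    sorted(result.removed.items()),
                    columns=["reason", "removed"],
                ),
                filter_report_path,
            )
        filter_counts = dict(result.removed)
        filter_counts["kept"] = len(kept)
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- cnv ---------------------------------------------------------------
    stage = "cnv"
    windows_path = outdir / "windows.tsv"
    segments_path = outdir / "segments.bed"
    try:
        track = read_depth(cfg.depth)
        windows = window_depth(track, ref, window=cfg.window)
        windows = normalize(windows)
        windows = mask_artifacts(windows, low_ratio=cfg.low_ratio, n_min=cfg.n_min)
        seg_result = segment(
            windows, cfg.baseline_ploidy, c_max=cfg.c_max, min_seg=cfg.min_seg
        )
        if force or not _stage_done([windows_path, segments_path]):
            wtab = windows.copy()
            if ref.centromeres:
                wtab["centromere"] = [
                    int(ref.centromeres.get(c, -1)) for c in wtab["chrom"]
                ]
            write_tsv(wtab, windows_path)
            write_bed(
                [
                    (s.chrom, s.start, s.end,
                     f"cn{s.copy_number}|{s.status}|ratio={s.mean_ratio:.3f}")
                    for s in seg_result.segments + seg_result.artifact_segments
                ],
                segments_path,
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- ploidy ------------------------------------------------------------
    stage = "ploidy"
    ploidy_path = outdir / "ploidy_report.tsv"
    spectrum_path = outdir / "spectrum.tsv"
    try:
        calls, report = segment_ploidy(
            kept, seg_result, cfg.baseline_ploidy,
            min_sites=cfg.min_sites,
            min_support=cfg.filter.min_support,
            include_indels=cfg.include_indels,
            k_max=cfg.k_max,
        )
        if force or not _stage_done([ploidy_path, spectrum_path]):
            write_tsv(pd.DataFrame(report), ploidy_path)
            from .af_ploidy import build_spectrum, collect_afs

            afs = collect_afs(kept, min_support=cfg.filter.min_support,
                              include_indels=cfg.include_indels)
            spec = build_spectrum(afs, region_label="all")
            write_tsv(
                pd.DataFrame(
                    {
                        "bin_start": spec.bin_edges[:-1],
                        "bin_end": spec.bin_edges[1:],
                        "count": spec.counts,
                        "region_label": spec.region_label,
                    }
                ),
                spectrum_path,
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # --- landscape ---------------------------------------------------------
    stage = "landscape"
    landscape_path = outdir / "landscape.tsv"
    effects_path = outdir / "effects.tsv"
    try:
        genes = read_gff3(cfg.gff3)
        density = density_track(kept, ref, window=cfg.window)
        indels = [r for r in kept if r.vtype == "InDel"]
        mod3 = indel_mod3_bias(indels, genes)
        fasta = Fasta(cfg.reference)
        effects = classify_effects(kept, genes, fasta)
        effect_counts = (
            pd.Series([e.effect for e in effects]).value_counts().to_dict()
        )
        if force or not _stage_done([landscape_path, effects_path]):
            write_tsv(density, landscape_path)
            write_tsv(
                pd.DataFrame(
                    [(e.chrom, e.pos, e.effect, e.gene_id or ".") for e in effects],
                    columns=["chrom", "pos", "effect", "gene_id"],
                ),
                effects_path,
            )
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    report_obj = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "filter": filter_counts,
        "segments": segments_to_frame(seg_result).to_dict(orient="records"),
        "ploidy": report,
        "density_summary": {
            "snv_total": int(density["snv_count"].sum()),
            "indel_total": int(density["indel_count"].sum()),
            "windows": int(len(density)),
        },
        "mod3_bias": {
            "p_cds": mod3.p_cds,
            "p_noncds": mod3.p_noncds,
            "diff": mod3.diff,
            "p_value": mod3.p_value,
            "method": mod3.method,
            "n_cds": mod3.n_cds,
            "n_noncds": mod3.n_noncds,
        },
        "effects": effect_counts,
    }
    report_path = outdir / "report.json"
    if force or not report_path.exists():
        with open(report_path, "w") as fh:
            json.dump(report_obj, fh, indent=1, sort_keys=True)
    if plots:
        from .plots import plot_af_spectrum, plot_coverage, plot_density

        plot_coverage(windows, outdir / "coverage.png")
        afs = collect_afs(kept, min_support=cfg.filter.min_support)
        plot_af_spectrum(build_spectrum(afs), outdir / "af_spectrum.png")
        plot_density(density, outdir / "density.png")
    logger.info("pipeline complete: %s", outdir / "report.json")
    return report_obj
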