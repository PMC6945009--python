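"""Hard filtering of raw SNV/InDel calls.

Implements the GATK-recommended hard-filter expressions for germline calls:
an SNV is removed when QD < 2.0, FS > 60.0 or MQ < 40; an InDel when
QD < 2.0 or FS > 200.0.  On top of the annotation rules, InDels longer than
100 bp and variants supported by fewer than five reads are dropped.  Values
exactly at a threshold are kept (the removal expressions are strict
inequalities).  Removal reasons are assigned in a fixed order
(missing-annotation, QD, FS, MQ, length, support) so reports are
deterministic.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .core_io import VariantRecord

__all__ = ["FilterConfig", "FilterResult", "filter_variants"]

logger = logging.getLogger(__name__)

REASONS = ("missing-annotation", "QD", "FS", "MQ", "length", "support")


@dataclass
class FilterConfig:
    """Thresholds for the hard-filter rules.

    ``support_mode`` selects how "supported by at least N reads" is counted:
    ``"ad_sum"`` (default) uses AD_ref + AD_alt, the informative reads for the
    called alleles; ``"dp"`` uses the raw FORMAT/DP.
    """

    snv_qd_min: float = 2.0
    snv_fs_max: float = 60.0
    snv_mq_min: float = 40.0
    indel_qd_min: float = 2.0
    indel_fs_max: float = 200.0
    indel_max_len: int = 100
    min_support: int = 5
    support_mode: str = "ad_sum"

    def __post_init__(self) -> None:
        for name in ("snv_qd_min", "snv_fs_max", "snv_mq_min",
                     "indel_qd_min", "indel_fs_max", "indel_max_len",
                     "min_support"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.support_mode not in ("ad_sum", "dp"):
            raise ValueError(f"unknown support_mode {self.support_mode!r}")


@dataclass
class FilterResult:
    kept: list[VariantRecord]
    removed: Counter

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())


def removal_reason(rec: VariantRecord, cfg: FilterConfig) -> str | None:
    """First failing rule for ``rec`` under ``cfg``, or None if kept."""
    if rec.missing:
        return "missing-annotation"
    if rec.vtype == "SNV":
        if rec.qd < cfg.snv_qd_min:
            return "QD"
        if rec.fs > cfg.snv_fs_max:
            return "FS"
        if rec.mq < cfg.snv_mq_min:
            return "MQ"
    else:
        if rec.qd < cfg.indel_qd_min:
            return "QD"
        if rec.fs > cfg.indel_fs_max:
            return "FS"
        if rec.indel_length > cfg.indel_max_len:
            return "length"
    support = rec.support if cfg.support_mode == "ad_sum" else rec.dp
    if support < cfg.min_support:
        return "support"
    return None


def filter_variants(
    records: Iterable[VariantRecord],
    cfg: FilterConfig | None = None,
) -> FilterResult:
    """Apply the hard-filter rules, returning kept records and a removal
    report keyed by the first failing rule."""
    cfg = cfg or FilterConfig()
    kept: list[VariantRecord] = []
    removed: Counter = Counter()
    n_missing = 0
    for rec in records:
        reason = removal_reason(rec, cfg)
        if reason is None:
            kept.append(rec)
        else:
            removed[reason] += 1
            if reason == "missing-annotation":
                n_missing += 1
    if n_missing:
        warnings.warn(
            f"{n_missing} record(s) removed for missing QD/FS/MQ annotations",
            stacklevel=2,
        )
    logger.info(
        "filter: kept %d, removed %d (%s)",
        len(kept), sum(removed.values()),
        ", ".join(f"{k}={removed[k]}" for k in REASONS if removed[k]),
    )
    return FilterResult(kept=kept, removed=removed)
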