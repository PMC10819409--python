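"""Copy-number variant screening: dual-caller concordance and the
de novo / unintended categorisation.

CNV call sets from two independent read-depth callers are reconciled by
reciprocal overlap (the field's usual ≥50% criterion) after a strict >1 kb
size filter. Retained calls are then categorised: present in the parental
line (not de novo), large rare events (3–10 Mb, standing in for
chromosome-scale abnormalities), events hitting coding exons, or other
de novo events — in that fixed precedence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import GenomicInterval

CNV_TYPES = ("deletion", "duplication")
CATEGORIES = ("not_de_novo", "large_rare", "exonic", "other_de_novo")


@dataclass(frozen=True)
class CnvCall:
    interval: GenomicInterval
    cnv_type: str
    source: str  # caller label; "a+b" after concordance merge

    def __post_init__(self) -> None:
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"invalid cnv_type {self.cnv_type!r}")

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class CnvConfig:
    min_size: int = 1000  # strict: retain size > min_size
    min_reciprocal_overlap: float = 0.5
    large_rare_min: int = 3_000_000
    large_rare_max: int = 10_000_000

    def __post_init__(self) -> None:
        if not (0.0 < self.min_reciprocal_overlap <= 1.0):
            raise ValueError("min_reciprocal_overlap must be in (0, 1]")
        if self.large_rare_min >= self.large_rare_max:
            raise ValueError("large_rare_min must be < large_rare_max")


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 when disjoint or cross-contig."""
    if a.contig != b.contig:
        return 0.0
    ovl = min(a.end, b.end) - max(a.start, b.start) + 1
    if ovl <= 0:
        return 0.0
    return min(ovl / len(a), ovl / len(b))


def _supported(call: CnvCall, others: list[CnvCall], min_ro: float) -> bool:
    return any(
        o.cnv_type == call.cnv_type
        and reciprocal_overlap(call.interval, o.interval) >= min_ro
        for o in others
    )


def concordant_cnvs(
    calls_a: list[CnvCall],
    calls_b: list[CnvCall],
    config: CnvConfig | None = None,
    require_concordance: bool = True,
) -> list[CnvCall]:
    """Calls from set A longer than ``min_size`` and (unless
    ``require_concordance`` is off, the single-caller mode) reciprocally
    supported by a same-type call in set B. Retained calls carry both
    callers' labels."""
    config = config or CnvConfig()
    sources_b = sorted({c.source for c in calls_b}) if calls_b else []
    retained = []
    for call in calls_a:
        if len(call) <= config.min_size:
            continue
        if require_concordance and not _supported(
            call, calls_b, config.min_reciprocal_overlap
        ):
            continue
        label = "+".join([call.source] + [s for s in sources_b if s != call.source])
        retained.append(CnvCall(call.interval, call.cnv_type, label or call.source))
    retained.sort(key=lambda c: (c.interval.contig, c.interval.start, c.interval.end))
    return retained


def classify_unintended(
    cnv: CnvCall,
    parent_calls: list[CnvCall],
    coding_exons: list[GenomicInterval],
    config: CnvConfig | None = None,
) -> str:
    """Category of a retained CNV under the fixed precedence
    not_de_novo -> large_rare -> exonic -> other_de_novo."""
    config = config or CnvConfig()
    if _supported(cnv, parent_calls, config.min_reciprocal_overlap):
        return "not_de_novo"
    if config.large_rare_min <= len(cnv) <= config.large_rare_max:
        return "large_rare"
    if any(cnv.interval.overlaps(exon) for exon in coding_exons):
        return "exonic"
    return "other_de_novo"
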