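"""Clone-vs-parent small-variant screen.

A variant is a candidate unintended edit when the derived clone carries a
heterozygous alternative genotype while the parental line is homozygous
reference, the caller's FILTER is PASS, and the call clears read-depth and
allele-fraction floors. The thresholds are read literally: *below* 10x and
*below* 0.2 are excluded, so DP = 10 and AF = 0.2 are retained.

Indels whose length change reaches 50 bp are reported as structural-variant
class in summaries, matching the usual SV size convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genome_io import GenomicInterval

SV_SIZE_BOUNDARY = 50  # |len(ref) - len(alt)| at or above this is SV-scale

#: Exclusion rules in the fixed order in which the first failure is tallied.
EXCLUSION_ORDER = (
    "filter",
    "zygosity_unknown",
    "genotype_pattern",
    "depth",
    "allele_fraction",
)


def classify_variant(ref: str, alt: str) -> str:
    """SNV / MNV / insertion / deletion from allele lengths."""
    if not ref or not alt:
        raise ValueError("empty allele")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


@dataclass(frozen=True)
class VariantRecord:
    """One clone/parent variant call for a single ALT allele."""

    interval: GenomicInterval
    ref: str
    alt: str
    clone_genotype: str  # hom_ref | het | hom_alt | unknown
    parent_genotype: str
    filter_status: str  # "PASS" or a named failure
    clone_depth: int | None  # None = unknown
    clone_allele_fraction: float | None  # None = unknown
    variant_class: str = ""

    def __post_init__(self) -> None:
        if set(self.ref) - set("ACGT") or set(self.alt) - set("ACGT"):
            raise ValueError(f"alleles must be over ACGT: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.interval}")
        expected = classify_variant(self.ref, self.alt)
        if self.variant_class and self.variant_class != expected:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {expected})"
            )
        if not self.variant_class:
            object.__setattr__(self, "variant_class", expected)

    @property
    def is_sv_scale(self) -> bool:
        return abs(len(self.ref) - len(self.alt)) >= SV_SIZE_BOUNDARY

    @property
    def key(self) -> tuple:
        return (self.interval.contig, self.interval.start, self.ref, self.alt)


@dataclass(frozen=True)
class ScreenThresholds:
    min_depth: int = 10
    min_allele_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not (0.0 <= self.min_allele_fraction <= 1.0):
            raise ValueError("min_allele_fraction must be in [0, 1]")


def failing_rule(record: VariantRecord, thresholds: ScreenThresholds) -> str | None:
    """First screen rule the record fails, in the fixed tally order, or None."""
    if record.filter_status != "PASS":
        return "filter"
    if record.clone_genotype == "unknown" or record.parent_genotype == "unknown":
        return "zygosity_unknown"
    if record.clone_genotype != "het" or record.parent_genotype != "hom_ref":
        return "genotype_pattern"
    if record.clone_depth is None or record.clone_depth < thresholds.min_depth:
        return "depth"
    if (
        record.clone_allele_fraction is None
        or record.clone_allele_fraction < thresholds.min_allele_fraction
    ):
        return "allele_fraction"
    return None


def screen_unique_variants(
    records: list[VariantRecord],
    thresholds: ScreenThresholds | None = None,
) -> tuple[list[VariantRecord], Counter]:
    """Split records into the retained "unique variant" set and an exclusion
    tally counting each excluded record under its first failing rule."""
    thresholds = thresholds or ScreenThresholds()
    retained: list[VariantRecord] = []
    tally: Counter = Counter({rule: 0 for rule in EXCLUSION_ORDER})
    for rec in records:
        rule = failing_rule(rec, thresholds)
        if rule is None:
            retained.append(rec)
        else:
            tally[rule] += 1
    return retained, tally
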