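"""Cross-referencing of screened variants with predicted sites, and the
PAM-free mismatch string search.

Two complementary detectors link variants to possible cleavage activity:

* :func:`crossref_sites` intersects a window flanking each variant (default
  200 bp each side) with the predicted site list, labelling hits on-target
  when the variant lies within a configurable radius (default 2 kb) of the
  intended target interval.
* :func:`string_search_screen` drops the PAM requirement entirely and scans
  the flank of each variant for the plain guide sequence, forward and
  reverse-complement, with up to 4 substitutions and no gaps. Because it
  ignores the PAM it can recover edited loci whose guides were designed
  against non-reference (e.g. patient-specific) sequence and are therefore
  missed by PAM-anchored prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from intervaltree import IntervalTree

from .genome_io import Contig, GenomicInterval
from .offtarget_search import GuideQuery, OfftargetSite, reverse_complement
from .variant_screen import VariantRecord


@dataclass(frozen=True)
class CrossrefConfig:
    window: int = 200  # bp flanking each side of a variant
    on_target_radius: int = 2000  # bp around the intended target interval
    string_search_max_mismatches: int = 4

    def __post_init__(self) -> None:
        if min(self.window, self.on_target_radius, self.string_search_max_mismatches) < 0:
            raise ValueError("crossref parameters must be non-negative")


@dataclass(frozen=True)
class CrossrefHit:
    variant: VariantRecord
    site: OfftargetSite
    distance: int  # bp between variant span and site span; 0 if overlapping
    label: str  # on_target | off_target_candidate


@dataclass(frozen=True)
class StringSearchHit:
    variant: VariantRecord
    match_interval: GenomicInterval
    orientation: str  # plus | minus
    mismatches: int


def variant_label(
    variant: VariantRecord,
    target_interval: GenomicInterval | None,
    config: CrossrefConfig,
) -> str:
    """on_target iff the variant lies within ``on_target_radius`` of the
    intended target interval (overlap counts as distance 0)."""
    if target_interval is not None:
        d = variant.interval.distance_to(target_interval)
        if d is not None and d <= config.on_target_radius:
            return "on_target"
    return "off_target_candidate"


def crossref_sites(
    variants: list[VariantRecord],
    sites: list[OfftargetSite],
    target_interval: GenomicInterval | None = None,
    config: CrossrefConfig | None = None,
) -> list[CrossrefHit]:
    """One hit per (variant, site) pair whose spans come within ``window`` bp.

    The site span includes the PAM. Variants on contigs absent from the site
    list's genome raise a warning and are reported unlinked (no hit).
    """
    config = config or CrossrefConfig()
    trees: dict[str, IntervalTree] = {}
    for idx, site in enumerate(sites):
        span = site.span_with_pam()
        # half-open tree coordinates over the closed genomic span
        trees.setdefault(span.contig, IntervalTree()).addi(span.start, span.end + 1, idx)
    site_contigs = set(trees)

    hits: list[CrossrefHit] = []
    for variant in variants:
        contig = variant.interval.contig
        if site_contigs and contig not in site_contigs:
            warnings.warn(
                f"variant contig {contig!r} absent from predicted-site genome; "
                "variant reported unlinked",
                stacklevel=2,
            )
            continue
        lo = max(1, variant.interval.start - config.window)
        hi = variant.interval.end + config.window
        label = variant_label(variant, target_interval, config)
        found = trees.get(contig, IntervalTree()).overlap(lo, hi + 1)
        for iv in sorted(found, key=lambda t: (t.begin, t.data)):
            site = sites[iv.data]
            dist = variant.interval.distance_to(site.span_with_pam())
            hits.append(CrossrefHit(variant, site, dist, label))
    hits.sort(
        key=lambda h: (
            h.variant.interval.contig,
            h.variant.interval.start,
            h.site.interval.start,
        )
    )
    return hits


def _scan_window(window_seq: str, pattern: str, max_mismatches: int):
    """Ungapped scan: yield (0-based offset, mismatches) of qualifying
    placements; windows containing N never match."""
    L = len(pattern)
    for off in range(len(window_seq) - L + 1):
        sub = window_seq[off : off + L]
        if "N" in sub:
            continue
        mm = sum(1 for a, b in zip(sub, pattern) if a != b)
        if mm <= max_mismatches:
            yield off, mm


def string_search_screen(
    genome: list[Contig],
    guide: GuideQuery,
    variants: list[VariantRecord],
    config: CrossrefConfig | None = None,
) -> list[StringSearchHit]:
    """PAM-free ungapped search of each variant's flank for the guide
    sequence in both orientations, up to the configured mismatch budget."""
    config = config or CrossrefConfig()
    by_name = {c.name: c for c in genome}
    hits: list[StringSearchHit] = []
    for variant in variants:
        contig = by_name.get(variant.interval.contig)
        if contig is None:
            raise ValueError(
                f"variant contig {variant.interval.contig!r} not in genome"
            )
        if variant.interval.end > len(contig):
            raise ValueError(
                f"variant at {variant.interval.contig}:{variant.interval.start} "
                "beyond contig end"
            )
        lo = max(1, variant.interval.start - config.window)  # 1-based
        hi = min(len(contig), variant.interval.end + config.window)
        window_seq = contig.sequence[lo - 1 : hi]
        for orientation, pattern in (
            ("plus", guide.protospacer),
            ("minus", reverse_complement(guide.protospacer)),
        ):
            for off, mm in _scan_window(
                window_seq, pattern, config.string_search_max_mismatches
            ):
                hits.append(
                    StringSearchHit(
                        variant=variant,
                        match_interval=GenomicInterval(
                            contig.name,
                            lo + off,
                            lo + off + len(pattern) - 1,
                            "+" if orientation == "plus" else "-",
                        ),
                        orientation=orientation,
                        mismatches=mm,
                    )
                )
    hits.sort(
        key=lambda h: (
            h.variant.interval.contig,
            h.variant.interval.start,
            h.match_interval.start,
            h.orientation,
        )
    )
    return hits
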