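"""Ensemble off-target prediction: run several search profiles, merge results.

Mimics the practice of running multiple off-target prediction tools and
pooling their output into one comprehensive, deduplicated site list. Each
profile is a (max mismatches, max bulge) budget modelled on a published
command-line predictor; sites found by several profiles are merged on
(contig, start, end, strand) and carry every admitting profile in their
``sources`` set, so provenance stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import Contig
from .offtarget_search import GuideQuery, OfftargetSite, SearchProfile, find_sites

#: The four default profiles: mismatch/bulge budgets of the four predictors
#: commonly combined for ensemble prediction (bulge "n/a" = bulges disallowed).
DEFAULT_PROFILES: tuple[SearchProfile, ...] = (
    SearchProfile("chopchop", max_mismatches=3, max_bulge=0),
    SearchProfile("cas-offinder", max_mismatches=5, max_bulge=2),
    SearchProfile("crispritz", max_mismatches=5, max_bulge=2),
    SearchProfile("crispr-offinder", max_mismatches=5, max_bulge=0),
)


@dataclass(frozen=True)
class EnsembleConfig:
    profiles: tuple[SearchProfile, ...] = DEFAULT_PROFILES

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("at least one search profile is required")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError(f"profile names must be unique: {names}")


def predict_offtargets(
    genome: list[Contig],
    guide: GuideQuery,
    config: EnsembleConfig | None = None,
) -> list[OfftargetSite]:
    """Union of per-profile :func:`find_sites`, deduplicated with provenance.

    Each surviving site keeps the minimal-cost alignment over the admitting
    profiles (identical by construction, since every profile reports the
    minimal-cost alignment for a locus it admits and a looser budget can
    only match or improve it — the loosest admitting profile's record wins).
    """
    config = config or EnsembleConfig()
    merged: dict[tuple, OfftargetSite] = {}
    for profile in config.profiles:
        for site in find_sites(genome, guide, profile):
            prev = merged.get(site.key)
            if prev is None:
                merged[site.key] = site
            else:
                prev.sources |= site.sources
                # keep the cheaper alignment record of the two
                cand_cost = (site.mismatches, site.dna_bulge + site.rna_bulge)
                prev_cost = (prev.mismatches, prev.dna_bulge + prev.rna_bulge)
                if cand_cost < prev_cost:
                    site.sources = prev.sources | site.sources
                    merged[site.key] = site
    return sorted(merged.values(), key=lambda s: s.key)
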