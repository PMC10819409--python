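"""Bundled reference cohort: a published WGS survey of 16 CRISPR/Cas-edited
human iPSC clones (hg19 coordinates).

The tables ship with the package and cover: per-clone WGS summaries
(coverage and clone-unique SNV/indel/SV counts), the engineered loci with
their Cas protein and delivery method, the guide library (protospacer + PAM),
the variants detected at or near the target sites, the genome-wide unintended
variants found by unbiased WGS analysis, and two validated mono-allelic
on-target deletions. They serve both as worked-example inputs and as ground
truth for the cohort statistics.

Unintended-event convention: one event per genome-wide WGS variant row plus
one event per clone with an unintended on-target modification (rows flagged
``intended = no``; a linked insertion+deletion at one locus counts once).
Clones whose IDs contain "CNC" are CRISPR-not-corrected (targeted but not
edited at the intended locus); all others are corrected (CC) clones.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort_stats import CloneRecord
from .genome_io import GenomicInterval
from .offtarget_search import GuideQuery
from .variant_screen import VariantRecord


def _load(name: str) -> pd.DataFrame:
    with resources.files("crisprqc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_clone_summaries() -> pd.DataFrame:
    """Per-clone WGS coverage and unique SNV/indel/SV counts (16 clones)."""
    return _load("clone_summaries.tsv")


def load_engineered_loci() -> pd.DataFrame:
    """One row per clone: gene, edited locus, Cas protein, delivery method,
    and the intended target-site interval."""
    return _load("engineered_loci.tsv")


def load_guides() -> list[GuideQuery]:
    """The guide library: protospacer, observed PAM, and PAM side."""
    df = _load("guides.tsv")
    return [
        GuideQuery(r.guide_id, r.protospacer, r.pam, r.pam_side, r.cas_label)
        for r in df.itertuples()
    ]


def load_ontarget_variants() -> pd.DataFrame:
    """Variants detected at or near the engineered target sites, with an
    ``intended`` flag (intended silent/screening edits and the intended
    disease-variant insertions vs unintended on-target modifications)."""
    return _load("ontarget_variants.tsv")


def load_wgs_variants() -> pd.DataFrame:
    """Genome-wide unintended variants found by unbiased WGS analysis."""
    return _load("wgs_variants.tsv")


def load_ontarget_deletions() -> pd.DataFrame:
    """Two validated mono-allelic on-target deletions (closed intervals)."""
    return _load("ontarget_deletions.tsv")


def clone_class(clone_id: str) -> str:
    return "CNC" if "CNC" in clone_id else "CC"


def target_intervals() -> dict[str, GenomicInterval]:
    """Intended target-site interval per clone."""
    loci = load_engineered_loci()
    return {
        r.clone_id: GenomicInterval(r.target_contig, r.target_start, r.target_end)
        for r in loci.itertuples()
    }


def unintended_event_counts() -> dict[str, int]:
    """Per-clone unintended-event tallies under the bundled convention."""
    summaries = load_clone_summaries()
    counts = {cid: 0 for cid in summaries.clone_id}
    for r in load_wgs_variants().itertuples():
        counts[r.clone_id] += 1
    ontarget = load_ontarget_variants()
    for r in ontarget[ontarget.intended == "no"].itertuples():
        counts[r.clone_id] += 1
    return counts


def build_clone_records() -> list[CloneRecord]:
    """Assemble the 16 CloneRecords: summaries + metadata + event tallies."""
    summaries = load_clone_summaries()
    loci = load_engineered_loci().set_index("clone_id")
    events = unintended_event_counts()
    records = []
    for r in summaries.itertuples():
        meta = loci.loc[r.clone_id]
        records.append(
            CloneRecord(
                clone_id=r.clone_id,
                coverage=r.coverage,
                n_unique_snv=r.n_unique_snv,
                n_unique_indel=r.n_unique_indel,
                n_unique_sv=r.n_unique_sv,
                cas_label=meta.cas_label,
                delivery=meta.delivery,
                n_unintended_events=events[r.clone_id],
            )
        )
    return records


def ontarget_variant_records() -> list[tuple[str, VariantRecord]]:
    """The on-target variant coordinates as (clone_id, VariantRecord) pairs.

    The source tables print coordinates and variant types but not alleles;
    placeholder alleles spanning the printed interval are synthesized here
    (the one printed multi-nucleotide substitution, AGT>CTG, is used
    verbatim). Only the intervals matter for window cross-referencing.
    """
    out: list[tuple[str, VariantRecord]] = []
    for r in load_ontarget_variants().itertuples():
        span = r.end - r.start + 1
        if r.variant_type == "MNP":
            ref, alt = ("AGT", "CTG") if span == 3 else ("A" * span, "C" * span)
        elif r.variant_type == "insertion":
            ref, alt = "A", "A" + "G" * 71
        elif r.variant_type == "deletion":
            ref, alt = "A" * (span + 1), "A"
        else:
            ref, alt = "A", "G"
        out.append(
            (
                r.clone_id,
                VariantRecord(
                    interval=GenomicInterval(r.contig, r.start, r.start + len(ref) - 1),
                    ref=ref,
                    alt=alt,
                    clone_genotype="het",
                    parent_genotype="hom_ref",
                    filter_status="PASS",
                    clone_depth=40,
                    clone_allele_fraction=0.5,
                ),
            )
        )
    return out
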