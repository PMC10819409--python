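"""End-to-end orchestration: predict -> screen -> cross-reference -> CNV
screen -> summarize, with file-based stage boundaries.

Every stage reads and writes documented TSV/BED/VCF files so each can also
be run standalone from the CLI; the orchestrator wires them together and
writes a run manifest (package version, config echo, input checksums).
Outputs are a pure function of inputs + config; the only timestamps live in
the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .cnv_screen import CnvCall, CnvConfig, classify_unintended, concordant_cnvs
from .crossref import CrossrefConfig, crossref_sites, string_search_screen
from .ensemble import EnsembleConfig, predict_offtargets
from .genome_io import GenomicInterval, read_bed, read_fasta, read_variant_file, write_bed
from .offtarget_search import GuideQuery
from .variant_screen import ScreenThresholds, screen_unique_variants


def read_guide_table(path) -> list[GuideQuery]:
    """TSV with columns guide_id, protospacer, pam, pam_side[, cas_label]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"guide_id", "protospacer", "pam", "pam_side"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"guide table {path} lacks columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"guide table {path} is empty")
    return [
        GuideQuery(
            r.guide_id,
            r.protospacer,
            r.pam,
            r.pam_side,
            getattr(r, "cas_label", "") or "",
        )
        for r in df.itertuples()
    ]


def read_cnv_calls(path, source: str) -> list[CnvCall]:
    """BED-like caller output: name column holds deletion/duplication."""
    calls = []
    for iv, attrs in read_bed(path):
        calls.append(CnvCall(iv, attrs.get("name", "deletion"), source))
    return calls


@dataclass
class RunConfig:
    genome: str
    guides: str
    out_dir: str
    clone_vcf: str | None = None
    clone_sample: str = "CLONE"
    parent_sample: str = "PARENT"
    target_bed: str | None = None
    cnv_a: str | None = None
    cnv_b: str | None = None
    cnv_parent: str | None = None
    exons: str | None = None
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    crossref: CrossrefConfig = field(default_factory=CrossrefConfig)
    cnv: CnvConfig = field(default_factory=CnvConfig)
    seed: int = 0

    def validate(self) -> None:
        for label, p in (("genome", self.genome), ("guides", self.guides)):
            if not os.path.exists(p):
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        for p in (self.clone_vcf, self.target_bed, self.cnv_a, self.cnv_b,
                  self.cnv_parent, self.exons):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"input path does not exist: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sites_to_bed(sites, path) -> None:
    rows = []
    for s in sites:
        rows.append(
            (
                s.interval,
                dict(
                    name=f"{s.guide_id}|{','.join(sorted(s.sources))}",
                    score=s.mismatches,
                    mismatches=s.mismatches,
                    dna_bulge=s.dna_bulge,
                    rna_bulge=s.rna_bulge,
                    pam_seq=s.pam_seq,
                ),
            )
        )
    write_bed(rows, path, extra_columns=["mismatches", "dna_bulge", "rna_bulge", "pam_seq"])


def _variants_to_tsv(variants, path) -> None:
    df = pd.DataFrame(
        [
            dict(
                contig=v.interval.contig,
                start=v.interval.start,
                end=v.interval.end,
                ref=v.ref,
                alt=v.alt,
                variant_class=v.variant_class,
                clone_genotype=v.clone_genotype,
                parent_genotype=v.parent_genotype,
                filter_status=v.filter_status,
                clone_depth=v.clone_depth,
                clone_allele_fraction=v.clone_allele_fraction,
            )
            for v in variants
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def _load_targets(path) -> dict[str, GenomicInterval]:
    """Target intervals keyed by BED name column (guide_id)."""
    if path is None:
        return {}
    return {attrs.get("name", "."): iv for iv, attrs in read_bed(path)}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; returns a report dict (also written to
    the manifest). A stage failure leaves partial outputs plus a FAILED
    marker in the manifest and re-raises."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "crisprqc",
        "version": __version__,
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "config": _config_echo(config),
        "inputs": {
            p: _sha256(p)
            for p in [config.genome, config.guides, config.clone_vcf,
                      config.target_bed, config.cnv_a, config.cnv_b,
                      config.cnv_parent, config.exons]
            if p
        },
        "status": "RUNNING",
        "stages": {},
    }
    report: dict = {"outputs": {}, "counts": {}}
    try:
        genome = read_fasta(config.genome)
        guides = read_guide_table(config.guides)
        targets = _load_targets(config.target_bed)

        all_sites: dict[str, list] = {}
        for guide in guides:
            all_sites[guide.guide_id] = predict_offtargets(genome, guide, config.ensemble)
        sites_path = out / "predicted_sites.bed"
        _sites_to_bed([s for ss in all_sites.values() for s in ss], sites_path)
        report["outputs"]["predicted_sites"] = str(sites_path)
        report["counts"]["predicted_sites"] = sum(len(s) for s in all_sites.values())
        manifest["stages"]["predict"] = "OK"

        retained = []
        if config.clone_vcf:
            records = read_variant_file(
                config.clone_vcf, config.clone_sample, config.parent_sample
            )
            retained, tally = screen_unique_variants(records, config.thresholds)
            _variants_to_tsv(retained, out / "retained_variants.tsv")
            pd.DataFrame(
                [{"rule": k, "excluded": v} for k, v in tally.items()]
            ).to_csv(out / "screen_exclusions.tsv", sep="\t", index=False)
            report["outputs"]["retained_variants"] = str(out / "retained_variants.tsv")
            report["counts"]["variants_in"] = len(records)
            report["counts"]["variants_retained"] = len(retained)
            manifest["stages"]["screen_variants"] = "OK"

            hit_rows, ss_rows = [], []
            for guide in guides:
                target = targets.get(guide.guide_id)
                for h in crossref_sites(
                    retained, all_sites[guide.guide_id], target, config.crossref
                ):
                    hit_rows.append(
                        dict(
                            guide_id=guide.guide_id,
                            contig=h.variant.interval.contig,
                            variant_start=h.variant.interval.start,
                            site_start=h.site.interval.start,
                            site_end=h.site.interval.end,
                            site_strand=h.site.strand,
                            distance=h.distance,
                            label=h.label,
                        )
                    )
                for h in string_search_screen(genome, guide, retained, config.crossref):
                    ss_rows.append(
                        dict(
                            guide_id=guide.guide_id,
                            contig=h.variant.interval.contig,
                            variant_start=h.variant.interval.start,
                            match_start=h.match_interval.start,
                            match_end=h.match_interval.end,
                            orientation=h.orientation,
                            mismatches=h.mismatches,
                        )
                    )
            pd.DataFrame(hit_rows).to_csv(out / "crossref_hits.tsv", sep="\t", index=False)
            pd.DataFrame(ss_rows).to_csv(
                out / "string_search_hits.tsv", sep="\t", index=False
            )
            report["outputs"]["crossref_hits"] = str(out / "crossref_hits.tsv")
            report["outputs"]["string_search_hits"] = str(out / "string_search_hits.tsv")
            report["counts"]["crossref_hits"] = len(hit_rows)
            report["counts"]["string_search_hits"] = len(ss_rows)
            manifest["stages"]["crossref"] = "OK"

        if config.cnv_a and config.cnv_b:
            calls_a = read_cnv_calls(config.cnv_a, "caller_a")
            calls_b = read_cnv_calls(config.cnv_b, "caller_b")
            parent = (
                read_cnv_calls(config.cnv_parent, "parent") if config.cnv_parent else []
            )
            exons = [iv for iv, _ in read_bed(config.exons)] if config.exons else []
            kept = concordant_cnvs(calls_a, calls_b, config.cnv)
            rows = [
                dict(
                    contig=c.interval.contig,
                    start=c.interval.start,
                    end=c.interval.end,
                    cnv_type=c.cnv_type,
                    sources=c.source,
                    category=classify_unintended(c, parent, exons, config.cnv),
                )
                for c in kept
            ]
            pd.DataFrame(rows).to_csv(out / "cnv_screen.tsv", sep="\t", index=False)
            report["outputs"]["cnv_screen"] = str(out / "cnv_screen.tsv")
            report["counts"]["cnvs_retained"] = len(kept)
            manifest["stages"]["screen_cnv"] = "OK"

        manifest["status"] = "OK"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    report["manifest"] = str(out / "manifest.json")
    return report


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [enc(v) for v in obj]
        return obj

    return {f.name: enc(getattr(config, f.name)) for f in dataclasses.fields(config)}
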