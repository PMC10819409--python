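"""A complete seeded synthetic scenario for end-to-end pipeline runs.

One call writes everything `crisprqc run` needs — genome FASTA, guide table,
target BED, two-sample VCF, dual-caller CNV BEDs, exon BED — plus a
truth.jsonl recording every plant and its expected downstream outcome.

The default scenario emulates one edited clone: a 40-kb contig, a 20-nt
Cas9-style guide (NGG), a perfect on-target site inside the declared target
interval, planted off-target sites spanning the mismatch/bulge classes the
four default search profiles distinguish, one PAM-less decoy, and variants
engineered to exercise every screen rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ensemble import EnsembleConfig, predict_offtargets
from .fixtures import (
    PlantSpec,
    VariantScenario,
    plant_sites,
    simulate_cnv_calls,
    simulate_genome,
    simulate_variant_files,
)
from .genome_io import GenomicInterval, write_bed, write_fasta
from .offtarget_search import GuideQuery

GUIDE_LEN = 20

#: planted off-target classes: (mismatches, bulge_type, bulge_len, pam_valid)
PLANT_CLASSES = (
    (0, "none", 0, True),   # the on-target site
    (1, "none", 0, True),
    (3, "none", 0, True),   # admitted by every profile
    (4, "none", 0, True),   # excluded by the 3-mismatch profile
    (5, "none", 0, True),
    (2, "dna", 1, True),    # requires a bulge-capable profile
    (2, "rna", 1, True),
    (0, "none", 0, False),  # valid protospacer, broken PAM: never predicted
)


def default_guide(seed: int) -> GuideQuery:
    rng = np.random.default_rng(seed + 7)
    proto = "".join(rng.choice(list("ACGT"), size=GUIDE_LEN))
    return GuideQuery("sim-guide", proto, "NGG", "three_prime", "Cas9")


def build_scenario(seed: int):
    """Plant the default scenario; returns (genome, guide, specs, target)."""
    genome = simulate_genome(seed, [40_000], gc_fraction=0.41)
    guide = default_guide(seed)
    spacing = 2 * (GUIDE_LEN + 200) + 2_000  # no cross-talk between plants
    specs = []
    for k, (mm, btype, blen, pam_ok) in enumerate(PLANT_CLASSES):
        specs.append(
            PlantSpec(
                guide_id=guide.guide_id,
                contig=genome[0].name,
                position=1_000 + k * spacing,
                strand="+" if k % 2 == 0 else "-",
                n_mismatches=mm,
                bulge_type=btype,
                bulge_length=blen,
                pam_valid=pam_ok,
            )
        )
    genome, truth = plant_sites(genome, guide, specs, seed=seed)
    on_target = specs[0]
    target = GenomicInterval(
        genome[0].name, on_target.position, on_target.position + GUIDE_LEN - 1
    )
    return genome, guide, specs, target


def write_scenario(seed: int, out_dir) -> tuple[dict, dict]:
    """Write all scenario files; returns ({name: path}, truth-dict)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, guide, specs, target = build_scenario(seed)

    paths = {
        "genome": out / "genome.fa",
        "guides": out / "guides.tsv",
        "target_bed": out / "target.bed",
        "clone_vcf": out / "clone_parent.vcf",
        "cnv_a": out / "cnv_caller_a.bed",
        "cnv_b": out / "cnv_caller_b.bed",
        "cnv_parent": out / "cnv_parent.bed",
        "exons": out / "exons.bed",
        "truth": out / "truth.jsonl",
    }

    write_fasta(genome, paths["genome"])
    with open(paths["guides"], "w") as fh:
        fh.write("guide_id\tprotospacer\tpam\tpam_side\tcas_label\n")
        fh.write(
            f"{guide.guide_id}\t{guide.protospacer}\t{guide.pam_pattern}\t"
            f"{guide.pam_side}\t{guide.cas_label}\n"
        )
    write_bed([(target, {"name": guide.guide_id})], paths["target_bed"])

    sites = predict_offtargets(genome, guide, EnsembleConfig())
    var_truth = simulate_variant_files(
        seed,
        genome,
        sites,
        VariantScenario(target_interval=target),
        paths["clone_vcf"],
    )

    calls_a, calls_b, parent, exons, cnv_truth = simulate_cnv_calls(seed)
    for key, calls in (("cnv_a", calls_a), ("cnv_b", calls_b), ("cnv_parent", parent)):
        write_bed(
            [(c.interval, {"name": c.cnv_type}) for c in calls], paths[key]
        )
    write_bed([(iv, {"name": "exon"}) for iv in exons], paths["exons"])

    truth_records = []
    for s in specs:
        truth_records.append(
            dict(kind="site", contig=s.contig, position=s.position, strand=s.strand,
                 mismatches=s.n_mismatches, bulge_type=s.bulge_type,
                 bulge_length=s.bulge_length, pam_valid=s.pam_valid)
        )
    for v in var_truth.planted_variants:
        truth_records.append(dict(kind="variant", **v))
    for c in cnv_truth.planted_cnvs:
        truth_records.append(dict(kind="cnv", **c))
    with open(paths["truth"], "w") as fh:
        for rec in truth_records:
            fh.write(json.dumps(rec) + "\n")

    return paths, {"sites": specs, "variants": var_truth.planted_variants,
                   "cnvs": cnv_truth.planted_cnvs}
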