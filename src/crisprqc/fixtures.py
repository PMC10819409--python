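"""Deterministic synthetic fixtures with machine-readable ground truth.

Everything here is a pure function of its seed and parameters: random
genomes of a chosen GC content, guide matches planted with exactly requested
mismatch/bulge/PAM states, paired clone/parent variant calls engineered to
pass or fail specific screen rules, and dual-caller CNV call sets. The truth
table records what was planted and what every downstream stage is expected
to report, so the whole pipeline is testable without any external data.

Background sequence can contain accidental high-mismatch matches; truth
assertions about planted loci are therefore subset assertions, with full
output pinned separately by the search engine's enumeration oracle.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .genome_io import Contig, GenomicInterval
from .offtarget_search import IUPAC_SETS, GuideQuery, OfftargetSite, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantSpec:
    """One requested guide-match plant."""

    guide_id: str
    contig: str
    position: int  # 1-based genomic start of the protospacer alignment span
    strand: str = "+"
    n_mismatches: int = 0
    bulge_type: str = "none"  # none | dna | rna
    bulge_length: int = 0
    pam_valid: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.n_mismatches <= 8):
            raise ValueError("n_mismatches must be in 0-8")
        if self.bulge_type not in ("none", "dna", "rna"):
            raise ValueError(f"bad bulge_type {self.bulge_type!r}")
        if self.bulge_type == "none" and self.bulge_length:
            raise ValueError("bulge_length must be 0 without a bulge")
        if self.bulge_type != "none" and not (1 <= self.bulge_length <= 3):
            raise ValueError("bulge_length must be in 1-3")

    def span_length(self, guide_len: int) -> int:
        if self.bulge_type == "dna":
            return guide_len + self.bulge_length
        if self.bulge_type == "rna":
            return guide_len - self.bulge_length
        return guide_len


@dataclass
class TruthTable:
    planted_sites: list[PlantSpec] = field(default_factory=list)
    planted_variants: list[dict] = field(default_factory=list)
    planted_cnvs: list[dict] = field(default_factory=list)


def simulate_genome(
    seed: int,
    contig_lengths: list[int],
    gc_fraction: float = 0.41,
) -> list[Contig]:
    """IID random genome at the requested GC content (default ~ human)."""
    if any(n < 1000 for n in contig_lengths):
        raise ValueError("contig lengths must be >= 1000")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    return [
        Contig(
            f"ctg{i + 1}",
            rng.choice(_BASES, size=n, p=probs).tobytes().decode("ascii"),
        )
        for i, n in enumerate(contig_lengths)
    ]


def _concrete_pam(rng, pattern: str, valid: bool) -> str:
    """A PAM realization matching the IUPAC pattern, or violating it at its
    most constrained position when ``valid`` is False."""
    bases = [rng.choice(sorted(IUPAC_SETS[c])) for c in pattern]
    if not valid:
        constrained = min(range(len(pattern)), key=lambda i: len(IUPAC_SETS[pattern[i]]))
        allowed = IUPAC_SETS[pattern[constrained]]
        outside = sorted(set("ACGT") - allowed)
        if not outside:
            raise ValueError(f"PAM pattern {pattern!r} cannot be violated")
        bases[constrained] = rng.choice(outside)
    return "".join(bases)


def _realize_protospacer(rng, guide: GuideQuery, spec: PlantSpec) -> str:
    """Genomic text (guide orientation) realizing exactly the requested
    mismatches and bulge against the protospacer."""
    proto = list(guide.protospacer)
    L = len(proto)
    # substitutions on aligned positions; keep them off the bulge and spread
    if spec.bulge_type == "rna":
        skip_at = int(rng.integers(1, L - spec.bulge_length))
        aligned_guide_idx = [i for i in range(L) if not skip_at <= i < skip_at + spec.bulge_length]
    else:
        aligned_guide_idx = list(range(L))
    mm_positions = sorted(
        rng.choice(len(aligned_guide_idx), size=spec.n_mismatches, replace=False)
    )
    aligned = [proto[i] for i in aligned_guide_idx]
    for j in mm_positions:
        aligned[j] = rng.choice(sorted(set("ACGT") - {aligned[j]}))
    if spec.bulge_type == "dna":
        at = int(rng.integers(1, L))
        bulge = [rng.choice(sorted("ACGT")) for _ in range(spec.bulge_length)]
        aligned = aligned[:at] + bulge + aligned[at:]
    return "".join(aligned)


def plant_sites(
    genome: list[Contig],
    guide: GuideQuery,
    specs: list[PlantSpec],
    seed: int = 0,
) -> tuple[list[Contig], TruthTable]:
    """Overwrite each spec's locus with a sequence realizing the requested
    match state; overlapping constructs (protospacer + PAM) are a hard error."""
    rng = np.random.default_rng(seed)
    P = len(guide.pam_pattern)
    seqs = {c.name: bytearray(c.sequence, "ascii") for c in genome}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in seqs}

    for spec in specs:
        if spec.contig not in seqs:
            raise ValueError(f"unknown contig {spec.contig!r}")
        proto_text = _realize_protospacer(rng, guide, spec)
        pam_text = _concrete_pam(rng, guide.pam_pattern, spec.pam_valid)
        if guide.pam_side == "three_prime":
            construct = proto_text + pam_text
            proto_off = 0
        else:
            construct = pam_text + proto_text
            proto_off = P
        if spec.strand == "-":
            rc = reverse_complement(construct)
            # protospacer occupies [off, off+len) of construct -> mirrored in rc
            rc_off = len(construct) - proto_off - len(proto_text)
            start0 = spec.position - 1 - rc_off
            text = rc
        else:
            start0 = spec.position - 1 - proto_off
            text = construct
        end0 = start0 + len(text) - 1
        if start0 < 0 or end0 >= len(seqs[spec.contig]):
            raise ValueError(f"plant at {spec.contig}:{spec.position} out of bounds")
        for s, e in occupied[spec.contig]:
            if start0 <= e and s <= end0:
                raise ValueError(
                    f"plant at {spec.contig}:{spec.position} overlaps a previous plant"
                )
        occupied[spec.contig].append((start0, end0))
        seqs[spec.contig][start0 : end0 + 1] = text.encode("ascii")

    modified = [Contig(c.name, seqs[c.name].decode("ascii")) for c in genome]
    return modified, TruthTable(planted_sites=list(specs))


# ---------------------------------------------------------------------------
# paired clone/parent variant calls
# ---------------------------------------------------------------------------

#: screen-failure modes the generator can plant, with the VCF fields used
FAIL_MODES = ("filter", "zygosity_unknown", "genotype_pattern", "depth", "allele_fraction")


@dataclass(frozen=True)
class VariantScenario:
    n_linked_pass: int = 3
    linked_fail_rules: tuple[str, ...] = FAIL_MODES
    n_unlinked_pass: int = 3
    n_on_target: int = 1
    target_interval: GenomicInterval | None = None
    window: int = 200


def _pick_positions(rng, n, lo, hi, forbidden, min_gap=500):
    """n positions in [lo, hi] at least min_gap from forbidden intervals and
    from each other."""
    chosen: list[int] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place variant positions; genome too small")
        pos = int(rng.integers(lo, hi + 1))
        if any(s - min_gap <= pos <= e + min_gap for s, e in forbidden):
            continue
        if any(abs(pos - c) < min_gap for c in chosen):
            continue
        chosen.append(pos)
    return sorted(chosen)


def simulate_variant_files(
    seed: int,
    genome: list[Contig],
    sites: list[OfftargetSite],
    scenario: VariantScenario,
    out_path: str | os.PathLike,
    clone_sample: str = "CLONE",
    parent_sample: str = "PARENT",
) -> TruthTable:
    """Write one two-sample VCF (clone + parent, Mutect2-style) of planted
    SNVs in four classes — linked-pass, linked-fail (one per requested
    rule), unlinked-pass, and on-target — and return their truth labels."""
    rng = np.random.default_rng(seed)
    contig = genome[0]
    site_spans = [
        (s.span_with_pam().start, s.span_with_pam().end)
        for s in sites
        if s.interval.contig == contig.name
    ]
    if (scenario.n_linked_pass or scenario.linked_fail_rules) and not site_spans:
        raise ValueError("scenario requests linked variants but no sites on contig 1")

    truth = TruthTable()
    rows: list[dict] = []
    used: list[tuple[int, int]] = []

    def snv_at(pos: int) -> tuple[str, str]:
        ref = contig.sequence[pos - 1]
        if ref == "N":
            ref = "A"
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        return ref, alt

    def add(pos, expected_screen, expected_link, *, filt="PASS", clone_gt="0/1",
            parent_gt="0/0", dp=30, af=0.4):
        ref, alt = snv_at(pos)
        rows.append(
            dict(pos=pos, ref=ref, alt=alt, filt=filt, clone_gt=clone_gt,
                 parent_gt=parent_gt, dp=dp, af=af)
        )
        used.append((pos, pos))
        truth.planted_variants.append(
            dict(contig=contig.name, pos=pos, ref=ref, alt=alt,
                 expected_screen=expected_screen, expected_link=expected_link)
        )

    near = scenario.window - 20  # safely inside the crossref window
    linked_needed = scenario.n_linked_pass + len(scenario.linked_fail_rules)
    if linked_needed > len(site_spans):
        raise ValueError(
            f"scenario needs {linked_needed} linked variants but only "
            f"{len(site_spans)} sites are on contig 1"
        )
    span_order = rng.permutation(len(site_spans))

    for k in range(scenario.n_linked_pass):
        s, e = site_spans[span_order[k]]
        pos = max(1, s - int(rng.integers(10, near)))
        add(pos, "retained", "linked")
    for j, rule in enumerate(scenario.linked_fail_rules):
        s, e = site_spans[span_order[scenario.n_linked_pass + j]]
        pos = min(len(contig), e + int(rng.integers(10, near)))
        kw: dict = {}
        if rule == "filter":
            kw["filt"] = "germline"
        elif rule == "zygosity_unknown":
            kw["clone_gt"] = "./."
        elif rule == "genotype_pattern":
            kw["parent_gt"] = "0/1"
        elif rule == "depth":
            kw["dp"] = 9
        elif rule == "allele_fraction":
            kw["af"] = 0.19
        else:
            raise ValueError(f"unknown fail rule {rule!r}")
        add(pos, rule, "linked_fail", **kw)

    forbidden = [(s - scenario.window, e + scenario.window) for s, e in site_spans]
    forbidden += used
    if scenario.target_interval is not None:
        forbidden.append((scenario.target_interval.start, scenario.target_interval.end))
    for pos in _pick_positions(
        rng, scenario.n_unlinked_pass, 1, len(contig), forbidden
    ):
        add(pos, "retained", "unlinked")

    if scenario.n_on_target:
        if scenario.target_interval is None:
            raise ValueError("on-target variants need a target_interval")
        t = scenario.target_interval
        step = max(1, len(t) // (scenario.n_on_target + 1))
        for k in range(scenario.n_on_target):
            add(min(t.end, t.start + (k + 1) * step), "retained", "on_target")

    rows.sort(key=lambda r: r["pos"])
    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in genome:
            fh.write(f"##contig=<ID={c.name},length={len(c)}>\n")
        fh.write('##FILTER=<ID=germline,Description="Evidence in the parent">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AF,Number=A,Type=Float,Description="Allele fraction">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{clone_sample}\t{parent_sample}\n"
        )
        for r in rows:
            fh.write(
                f"{contig.name}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\t"
                f"{r['filt']}\t.\tGT:DP:AF\t"
                f"{r['clone_gt']}:{r['dp']}:{r['af']}\t"
                f"{r['parent_gt']}:{r['dp']}:0.0\n"
            )
    return truth


# ---------------------------------------------------------------------------
# CNV call sets
# ---------------------------------------------------------------------------

def simulate_cnv_calls(
    seed: int,
    contig: str = "cnv_ctg",
    contig_length: int = 100_000_000,
):
    """Dual-caller CNV call sets with known concordance and categories.

    Returns (calls_a, calls_b, parent_calls, exons, truth). Planted classes:
    concordant de novo large-rare, concordant de novo exonic, concordant
    de novo other, concordant not-de-novo, size-filtered (<= 1 kb), and an
    A-only call with no reciprocal B support.
    """
    from .cnv_screen import CnvCall

    rng = np.random.default_rng(seed)
    truth = TruthTable()
    calls_a: list[CnvCall] = []
    calls_b: list[CnvCall] = []
    parent: list[CnvCall] = []
    exons: list[GenomicInterval] = []

    def iv(start, length):
        return GenomicInterval(contig, start, start + length - 1)

    cursor = int(rng.integers(1_000, 10_000))
    gap = 12_000_000

    # de novo, 5 Mb -> large_rare
    calls_a.append(CnvCall(iv(cursor, 5_000_000), "deletion", "caller_a"))
    calls_b.append(CnvCall(iv(cursor + 1000, 5_000_000), "deletion", "caller_b"))
    truth.planted_cnvs.append(dict(start=cursor, retained=True, category="large_rare"))
    cursor += gap

    # de novo 2 kb hitting an exon -> exonic
    calls_a.append(CnvCall(iv(cursor, 2_000), "deletion", "caller_a"))
    calls_b.append(CnvCall(iv(cursor, 2_000), "deletion", "caller_b"))
    exons.append(iv(cursor + 500, 200))
    truth.planted_cnvs.append(dict(start=cursor, retained=True, category="exonic"))
    cursor += gap

    # de novo 50 kb, no exon -> other_de_novo
    calls_a.append(CnvCall(iv(cursor, 50_000), "duplication", "caller_a"))
    calls_b.append(CnvCall(iv(cursor + 2_000, 50_000), "duplication", "caller_b"))
    truth.planted_cnvs.append(dict(start=cursor, retained=True, category="other_de_novo"))
    cursor += gap

    # inherited 4 Mb -> not_de_novo
    calls_a.append(CnvCall(iv(cursor, 4_000_000), "deletion", "caller_a"))
    calls_b.append(CnvCall(iv(cursor, 4_000_000), "deletion", "caller_b"))
    parent.append(CnvCall(iv(cursor, 4_000_000), "deletion", "parent"))
    truth.planted_cnvs.append(dict(start=cursor, retained=True, category="not_de_novo"))
    cursor += gap

    # too small (800 bp) -> removed by the size rule
    calls_a.append(CnvCall(iv(cursor, 800), "deletion", "caller_a"))
    calls_b.append(CnvCall(iv(cursor, 800), "deletion", "caller_b"))
    truth.planted_cnvs.append(dict(start=cursor, retained=False, category="size"))
    cursor += gap

    # A-only 5 kb with 30% overlap in B -> removed by concordance
    calls_a.append(CnvCall(iv(cursor, 5_000), "deletion", "caller_a"))
    calls_b.append(CnvCall(iv(cursor + 3_500, 5_000), "deletion", "caller_b"))
    truth.planted_cnvs.append(dict(start=cursor, retained=False, category="discordant"))

    if cursor + 5_000 >= contig_length:
        raise ValueError("contig_length too small for the planted layout")
    return calls_a, calls_b, parent, exons, truth
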