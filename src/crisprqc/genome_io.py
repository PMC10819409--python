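"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 1-based inclusive throughout (the convention of VCF
and of published target-site tables); BED output converts to 0-based
half-open at the boundary and :func:`read_bed` converts back.

FASTA records are validated on load: sequences are uppercased (soft-masked
lowercase bases become searchable) and any character outside ``{A,C,G,T,N}``
is a hard error naming the offending position.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class Contig:
    """One reference contig: a name and an uppercase DNA sequence."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("contig name must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"contig {self.name!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval, 1-based inclusive on both ends."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int | None:
        """Gap in bp between two closed intervals; 0 if they overlap,
        None if on different contigs."""
        if self.contig != other.contig:
            return None
        return max(0, other.start - self.end, self.start - other.end)


def _validate_sequence(name: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        for i, c in enumerate(seq):
            if c in bad:
                raise ValueError(
                    f"contig {name!r}: invalid character {c!r} at position {i + 1}"
                )
    return seq


def read_fasta(path: str | os.PathLike) -> list[Contig]:
    """Read a (possibly wrapped, possibly soft-masked) FASTA file.

    Returns contigs in file order. Duplicate contig names and characters
    outside ``{A,C,G,T,N}`` (after uppercasing) are hard errors.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig name {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, _validate_sequence(rec.id, str(rec.seq))))
    return contigs


def write_fasta(contigs: list[Contig], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    intervals,
    path: str | os.PathLike,
    extra_columns: list[str] | None = None,
) -> None:
    """Write intervals (with optional per-interval attribute dicts) as BED.

    ``intervals`` is an iterable of either ``GenomicInterval`` or
    ``(GenomicInterval, dict)`` pairs; dict values become extra tab-separated
    columns in ``extra_columns`` order. Output is sorted by (contig, start)
    and uses 0-based half-open coordinates. An empty collection produces a
    file holding only the header comment.
    """
    rows = []
    for item in intervals:
        if isinstance(item, GenomicInterval):
            iv, attrs = item, {}
        else:
            iv, attrs = item
        rows.append((iv, attrs))
    rows.sort(key=lambda r: (r[0].contig, r[0].start, r[0].end, r[0].strand))
    extra_columns = extra_columns or []
    with open(path, "w") as fh:
        header = ["contig", "start", "end", "name", "score", "strand"] + extra_columns
        fh.write("#" + "\t".join(header) + "\n")
        for iv, attrs in rows:
            fields = [
                iv.contig,
                str(iv.start - 1),
                str(iv.end),
                str(attrs.get("name", ".")),
                str(attrs.get("score", ".")),
                iv.strand,
            ] + [str(attrs.get(col, ".")) for col in extra_columns]
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | os.PathLike) -> list[tuple[GenomicInterval, dict]]:
    """Read a BED(6+) file back into 1-based inclusive intervals."""
    out: list[tuple[GenomicInterval, dict]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            contig, start0, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) >= 6 and f[5] in _STRANDS else "."
            attrs: dict = {}
            if len(f) >= 4:
                attrs["name"] = f[3]
            if len(f) >= 5:
                attrs["score"] = f[4]
            if len(f) > 6:
                attrs["extra"] = f[6:]
            out.append((GenomicInterval(contig, start0 + 1, end, strand), attrs))
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variant_file(
    path: str | os.PathLike,
    clone_sample: str,
    parent_sample: str,
):
    """Load paired clone/parent small-variant calls from a VCF.

    One :class:`~crisprqc.variant_screen.VariantRecord` is produced per ALT
    allele (multi-allelic records are decomposed). The clone's allele
    fraction is taken from its ``AF`` FORMAT field when present, else
    computed from ``AD``, else recorded as unknown; depth comes from ``DP``.
    Missing values are screened out downstream, never guessed.
    """
    from cyvcf2 import VCF

    from .variant_screen import VariantRecord

    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    for s in (clone_sample, parent_sample):
        if s not in samples:
            raise ValueError(f"sample {s!r} not found in {path} (has {samples})")
    ci = samples.index(clone_sample)
    pi = samples.index(parent_sample)

    records: list[VariantRecord] = []
    for v in vcf:
        try:
            records.extend(_decompose(v, ci, pi))
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(
                f"malformed VCF record at {path} line for {v.CHROM}:{v.POS}: {exc}"
            ) from exc
    return records


def _genotype_wrt_alt(gt_indices, alt_index: int) -> str:
    """Zygosity of one sample with respect to one ALT allele (1-based index)."""
    alleles = [a for a in gt_indices if isinstance(a, int)]
    if len(alleles) < 2 or any(a < 0 for a in alleles):
        return "unknown"
    # per-allele decomposition: zygosity counts copies of this ALT only
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 0:
        return "hom_ref"
    if n_alt == len(alleles):
        return "hom_alt"
    return "het"


def _format_value(variant, tag: str, sample_index: int):
    try:
        arr = variant.format(tag)
    except KeyError:  # tag absent from the header entirely
        return None
    if arr is None:
        return None
    val = arr[sample_index]
    try:
        vals = [float(x) for x in val]
    except TypeError:
        vals = [float(val)]
    vals = [v for v in vals if v == v and v > -2147483648]  # drop NaN / missing
    return vals or None


def _decompose(v, clone_index: int, parent_index: int):
    from .variant_screen import VariantRecord, classify_variant

    genotypes = v.genotypes  # [[a, b, phased], ...]
    records = []
    dp = _format_value(v, "DP", clone_index)
    depth = int(dp[0]) if dp else None
    af = _format_value(v, "AF", clone_index)
    ad = _format_value(v, "AD", clone_index)
    filt = v.FILTER or "PASS"  # cyvcf2 reports PASS as None

    for ai, alt in enumerate(v.ALT, start=1):
        if af is not None and len(af) >= ai:
            frac = float(af[ai - 1]) if len(af) >= len(v.ALT) else float(af[0])
        elif ad is not None and len(ad) >= ai + 1:
            total = sum(ad)
            frac = ad[ai] / total if total > 0 else None
        else:
            frac = None
        clone_gt = _genotype_wrt_alt(genotypes[clone_index][:-1], ai)
        parent_gt = _genotype_wrt_alt(genotypes[parent_index][:-1], ai)
        records.append(
            VariantRecord(
                interval=GenomicInterval(v.CHROM, v.POS, v.POS + len(v.REF) - 1),
                ref=v.REF,
                alt=alt,
                clone_genotype=clone_gt,
                parent_genotype=parent_gt,
                filter_status=filt,
                clone_depth=depth,
                clone_allele_fraction=frac,
                variant_class=classify_variant(v.REF, alt),
            )
        )
    return records
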