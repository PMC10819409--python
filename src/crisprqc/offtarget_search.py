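"""Mismatch- and bulge-tolerant, PAM-aware genome search for guide targets.

The engine reports every genomic locus, on both strands, where a guide's
protospacer aligns with at most ``max_mismatches`` substitutions and at most
one interior bulge (a run of unpaired genomic bases — a DNA bulge — or of
unpaired guide bases — an RNA bulge) of length at most ``max_bulge``, with
the PAM pattern matched exactly (position-wise IUPAC, zero mismatches)
immediately adjacent on the correct side in strand orientation.

Conventions fixed here and enforced by the exhaustive oracle in the test
suite:

* PAM positions never count toward the mismatch budget and tolerate no
  mismatches.
* At most one bulge per alignment, of one type; bulges are strictly interior
  (a terminal bulge is equivalent to a shorter or shifted match and would
  double-count loci).
* A genomic ``N`` matches nothing — not even the pattern code ``N`` — so
  assembly gaps and masked regions never yield sites.
* Loci whose alignments share (contig, start, end, strand) are reported once
  with the minimal-cost alignment: fewest mismatches, then shortest bulge,
  then no-bulge over DNA bulge over RNA bulge, then leftmost bulge placement
  in guide orientation.

The scan itself is a vectorized sliding-window comparison (numpy), which on
the genome sizes this package targets is both simple and fast; behaviour is
pinned by oracle equivalence, not by the scanning strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import Contig, GenomicInterval

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_match(base: str, code: str) -> bool:
    """True iff ``base`` is in IUPAC ``code``'s set; genomic N matches no code."""
    if code not in IUPAC_SETS:
        raise ValueError(f"invalid IUPAC code {code!r}")
    if base == "N":
        return False
    if base not in "ACGT":
        raise ValueError(f"invalid base {base!r}")
    return base in IUPAC_SETS[code]


def reverse_complement(seq: str) -> str:
    """Reverse complement; defined for the full IUPAC alphabet."""
    for c in seq:
        if c not in IUPAC_SETS:
            raise ValueError(f"cannot complement invalid character {c!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideQuery:
    """A guide for one Cas system: protospacer, PAM pattern and PAM side."""

    guide_id: str
    protospacer: str
    pam_pattern: str
    pam_side: str  # "three_prime" (Cas9-style) or "five_prime" (Cas12a-style)
    cas_label: str = ""

    def __post_init__(self) -> None:
        if not (18 <= len(self.protospacer) <= 24):
            raise ValueError(
                f"guide {self.guide_id!r}: protospacer length "
                f"{len(self.protospacer)} outside 18-24"
            )
        bad = set(self.protospacer) - set("ACGT")
        if bad:
            raise ValueError(f"guide {self.guide_id!r}: invalid bases {sorted(bad)}")
        bad = set(self.pam_pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"guide {self.guide_id!r}: invalid PAM codes {sorted(bad)}")
        if self.pam_side not in ("three_prime", "five_prime"):
            raise ValueError(f"guide {self.guide_id!r}: bad pam_side {self.pam_side!r}")


@dataclass(frozen=True)
class SearchProfile:
    """One tool-style search budget: mismatch and single-bulge bounds."""

    name: str
    max_mismatches: int
    max_bulge: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.max_mismatches <= 8):
            raise ValueError("max_mismatches must be in 0-8")
        if not (0 <= self.max_bulge <= 3):
            raise ValueError("max_bulge must be in 0-3")


@dataclass
class OfftargetSite:
    """One predicted cleavage locus with its minimal-cost alignment."""

    guide_id: str
    interval: GenomicInterval
    strand: str
    mismatches: int
    dna_bulge: int
    rna_bulge: int
    pam_interval: GenomicInterval
    pam_seq: str
    aligned_genomic_seq: str
    sources: set[str] = field(default_factory=set)

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.interval.contig, self.interval.start, self.interval.end, self.strand)

    def span_with_pam(self) -> GenomicInterval:
        """Closed interval covering protospacer and PAM."""
        return GenomicInterval(
            self.interval.contig,
            min(self.interval.start, self.pam_interval.start),
            max(self.interval.end, self.pam_interval.end),
            self.strand,
        )


# ---------------------------------------------------------------------------
# alignment configurations
# ---------------------------------------------------------------------------

_TYPE_RANK = {"none": 0, "dna": 1, "rna": 2}


def _alignment_configs(guide_len: int, max_bulge: int):
    """Yield (bulge_type, bulge_len, placement, span, genomic_offsets, guide_idx).

    ``placement`` is the guide index immediately after which the bulge sits
    (DNA) or the first skipped guide index (RNA); bulges are strictly
    interior to the alignment.
    """
    L = guide_len
    yield ("none", 0, 0, L, np.arange(L), np.arange(L))
    for g in range(1, max_bulge + 1):
        # DNA bulge: g extra genomic bases between guide positions i-1 and i
        for i in range(1, L):
            offs = np.concatenate([np.arange(i), np.arange(i + g, L + g)])
            yield ("dna", g, i, L + g, offs, np.arange(L))
        # RNA bulge: guide positions i..i+g-1 unpaired (genome skips nothing)
        for i in range(1, L - g):
            gidx = np.concatenate([np.arange(i), np.arange(i + g, L)])
            yield ("rna", g, i, L - g, np.arange(L - g), gidx)


def _pam_match_vector(arr: np.ndarray, pattern: str) -> np.ndarray:
    """ok[j] = True iff the PAM pattern matches arr[j : j+len(pattern)]."""
    n = len(arr)
    P = len(pattern)
    if n < P:
        return np.zeros(0, dtype=bool)
    ok = np.ones(n - P + 1, dtype=bool)
    for k, code in enumerate(pattern):
        allowed = np.zeros(256, dtype=bool)
        for b in IUPAC_SETS[code]:
            allowed[ord(b)] = True  # genomic N stays disallowed
        ok &= allowed[arr[k : k + n - P + 1]]
    return ok


def _scan_forward(seq: str, guide: GuideQuery, profile: SearchProfile):
    """All minimal-cost qualifying alignments on the given sequence, read as
    the forward strand. Returns dicts keyed by 0-based (start, end)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    garr = np.frombuffer(guide.protospacer.encode("ascii"), dtype=np.uint8)
    n = len(arr)
    L = len(garr)
    P = len(guide.pam_pattern)
    pam_ok = _pam_match_vector(arr, guide.pam_pattern)
    is_n = arr == ord("N")

    best: dict[tuple[int, int], dict] = {}
    window_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    for btype, blen, place, span, offs, gidx in _alignment_configs(L, profile.max_bulge):
        if span > n:
            continue
        if span not in window_cache:
            W = np.lib.stride_tricks.sliding_window_view(arr, span)
            has_n = (
                np.lib.stride_tricks.sliding_window_view(is_n, span).any(axis=1)
                if is_n.any()
                else np.zeros(n - span + 1, dtype=bool)
            )
            window_cache[span] = (W, has_n)
        W, has_n = window_cache[span]
        n_pos = n - span + 1

        mism = (W[:, offs] != garr[gidx]).sum(axis=1)
        ok = (mism <= profile.max_mismatches) & ~has_n

        # exact PAM adjacent on the guide's PAM side (forward orientation)
        pam_adj = np.zeros(n_pos, dtype=bool)
        if guide.pam_side == "three_prime":
            hi = min(n_pos, len(pam_ok) - span)
            if hi > 0:
                pam_adj[:hi] = pam_ok[span : span + hi]
            pam_start_off = span
        else:
            if len(pam_ok) > 0:
                pam_adj[P : min(n_pos, len(pam_ok) + P)] = pam_ok[: max(0, n_pos - P)]
            pam_start_off = -P
        ok &= pam_adj

        cost_rank = (blen, _TYPE_RANK[btype], place)
        for p in np.nonzero(ok)[0]:
            key = (int(p), int(p) + span - 1)
            cand = {
                "mismatches": int(mism[p]),
                "bulge_type": btype,
                "bulge_len": blen,
                "placement": place,
                "pam_start": int(p) + pam_start_off,
            }
            prev = best.get(key)
            if prev is None or (cand["mismatches"], cost_rank) < (
                prev["mismatches"],
                (prev["bulge_len"], _TYPE_RANK[prev["bulge_type"]], prev["placement"]),
            ):
                best[key] = cand
    return best


def find_sites(
    genome: list[Contig],
    guide: GuideQuery,
    profile: SearchProfile,
) -> list[OfftargetSite]:
    """Search every contig, both strands, for sites admitted by ``profile``.

    Output is sorted by (contig, start, end, strand) with one entry per
    distinct locus.
    """
    if not genome:
        raise ValueError("empty genome")
    P = len(guide.pam_pattern)
    sites: list[OfftargetSite] = []
    for contig in genome:
        n = len(contig.sequence)
        for strand, seq in (("+", contig.sequence), ("-", reverse_complement(contig.sequence))):
            for (s0, e0), aln in _scan_forward(seq, guide, profile).items():
                ps0 = aln["pam_start"]
                pe0 = ps0 + P - 1
                if strand == "+":
                    iv = GenomicInterval(contig.name, s0 + 1, e0 + 1, "+")
                    pam_iv = GenomicInterval(contig.name, ps0 + 1, pe0 + 1, "+")
                else:
                    iv = GenomicInterval(contig.name, n - e0, n - s0, "-")
                    pam_iv = GenomicInterval(contig.name, n - pe0, n - ps0, "-")
                sites.append(
                    OfftargetSite(
                        guide_id=guide.guide_id,
                        interval=iv,
                        strand=strand,
                        mismatches=aln["mismatches"],
                        dna_bulge=aln["bulge_len"] if aln["bulge_type"] == "dna" else 0,
                        rna_bulge=aln["bulge_len"] if aln["bulge_type"] == "rna" else 0,
                        pam_interval=pam_iv,
                        pam_seq=seq[ps0 : pe0 + 1],
                        aligned_genomic_seq=seq[s0 : e0 + 1],
                        sources={profile.name},
                    )
                )
    sites.sort(key=lambda s: s.key)
    return sites
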