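"""Independent reference implementations used only to pin behaviour.

The site-enumeration oracle walks every window and every single-bulge gapped
alignment with plain Python string operations; the t-tail oracle integrates
the Student density numerically. Both are deliberately naive and share no
code with the package internals they check.
"""

import math

from scipy.integrate import quad

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(_RC[c] for c in reversed(seq))


def _enumerate_alignments(L, max_bulge):
    """(bulge_type, bulge_len, placement, aligned (genomic_offset, guide_index) pairs, span)"""
    yield "none", 0, 0, [(k, k) for k in range(L)], L
    for g in range(1, max_bulge + 1):
        for i in range(1, L):  # DNA bulge between guide i-1 and i
            pairs = [(k, k) for k in range(i)] + [(k + g, k) for k in range(i, L)]
            yield "dna", g, i, pairs, L + g
        for i in range(1, L - g):  # RNA bulge: guide i..i+g-1 skipped
            pairs = [(k, k) for k in range(i)] + [(k - g, k) for k in range(i + g, L)]
            yield "rna", g, i, pairs, L - g


def oracle_find_sites(genome, guide, max_mismatches, max_bulge):
    """Exhaustive enumeration; returns {(contig, start, end, strand):
    (mismatches, dna_bulge, rna_bulge)} with 1-based inclusive coordinates
    and minimal-cost canonicalization (mismatches, bulge length, no-bulge
    over DNA over RNA, leftmost placement)."""
    proto = guide.protospacer
    pam = guide.pam_pattern
    L, P = len(proto), len(pam)
    rank = {"none": 0, "dna": 1, "rna": 2}
    best = {}

    for contig in genome:
        n = len(contig.sequence)
        for strand in "+-":
            seq = contig.sequence if strand == "+" else rc(contig.sequence)
            for btype, g, place, pairs, span in _enumerate_alignments(L, max_bulge):
                for p in range(n - span + 1):
                    # exact PAM adjacent in guide orientation
                    if guide.pam_side == "three_prime":
                        pam_lo = p + span
                    else:
                        pam_lo = p - P
                    if pam_lo < 0 or pam_lo + P > n:
                        continue
                    pam_obs = seq[pam_lo : pam_lo + P]
                    if any(b == "N" or b not in IUPAC[c] for b, c in zip(pam_obs, pam)):
                        continue
                    window = seq[p : p + span]
                    if "N" in window:
                        continue
                    mm = 0
                    for off, gi in pairs:
                        if window[off] != proto[gi]:
                            mm += 1
                            if mm > max_mismatches:
                                break
                    if mm > max_mismatches:
                        continue
                    if strand == "+":
                        key = (contig.name, p + 1, p + span, "+")
                    else:
                        key = (contig.name, n - (p + span) + 1, n - p, "-")
                    cost = (mm, g, rank[btype], place)
                    if key not in best or cost < best[key][0]:
                        best[key] = (cost, btype, g)
    return {
        key: (cost[0], g if btype == "dna" else 0, g if btype == "rna" else 0)
        for key, (cost, btype, g) in best.items()
    }


def t_sf_by_integration(x, df):
    """Upper tail of Student's t by numerical integration of the density."""
    c = math.exp(
        math.lgamma((df + 1) / 2.0) - math.lgamma(df / 2.0)
    ) / math.sqrt(df * math.pi)

    def pdf(t):
        return c * (1.0 + t * t / df) ** (-(df + 1) / 2.0)

    upper, _ = quad(pdf, abs(x), math.inf, limit=200)
    return upper if x >= 0 else 1.0 - upper
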