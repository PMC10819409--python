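# Methods

This note documents the models, conventions and numerical choices behind
`crisprqc`, in the order the pipeline applies them.

## Coordinates and formats

Internal coordinates are 1-based inclusive on both ends, matching VCF and
the coordinate style of published target-site tables; BED files are
converted to/from 0-based half-open at the I/O boundary only. Interval
length is `end − start + 1`, and the distance between two closed intervals
is the gap between them (0 when they overlap). One consequence worth
stating: a deletion printed as `chr9:80,412,512–80,412,841` has inclusive
length 330 bp even where a source reports 329; the package standardizes on
inclusive lengths throughout (the other bundled deletion,
`chr20:62,068,445–62,070,301`, is inclusive-consistent at 1,857 bp).

Soft-masked (lowercase) genome sequence is uppercased on load and treated
as searchable; masking must not hide sites. `N` bases are kept but match
nothing (below).

## Off-target search model

A site is an alignment of the protospacer to the genome with

* at most `max_mismatches` substitutions on aligned positions,
* at most one bulge — a contiguous run of unpaired genomic bases (DNA
  bulge) or unpaired guide bases (RNA bulge) — of length ≤ `max_bulge`,
  strictly interior to the alignment, and
* the PAM pattern matched exactly, position-wise under IUPAC codes,
  immediately adjacent on the guide's PAM side in strand orientation
  (3′ for Cas9-style NGG, 5′ for Cas12a-style TTTV).

Conventions, chosen where the underlying tool literature is the guide:

* **PAM positions never consume mismatch budget and tolerate none.** This
  is the convention of the mismatch-bounded search tools the default
  profiles emulate.
* **One bulge, either type, same size bound.** The published budgets state
  a single bulge size; it is applied symmetrically to DNA and RNA bulges.
* **Terminal bulges are disallowed** — a bulge at either end of the
  alignment is equivalent to a shorter or shifted match and would
  double-count loci.
* **Genomic `N` matches nothing, including pattern code `N`.** Assembly
  gaps and hard-masked regions can therefore never produce predicted sites.
* **Canonicalization.** All alignments sharing (contig, start, end, strand)
  are reported once with the minimal-cost alignment: fewest mismatches,
  then shortest bulge, then no-bulge over DNA bulge over RNA bulge, then
  leftmost bulge placement in guide orientation.

The scan is a vectorized sliding-window comparison per alignment
configuration; the minus strand is searched on the reverse-complemented
contig and mapped back, which makes strand-mirror symmetry hold by
construction. Correctness is pinned by a deliberately naive exhaustive
enumeration oracle (per-window, per-configuration string comparison) that
shares no code with the engine; the test suite asserts exact equality of
site sets and accounting on dozens of seeded genomes for every default
profile.

The four default profiles, (3, 0), (5, 2), (5, 2), (5, 0), are the
mismatch/bulge budgets of four commonly combined command-line predictors
("n/a" bulge read as 0). The ensemble stage is a union with provenance:
sites are deduplicated on (contig, start, end, strand) and each retained
row lists every admitting profile. Bulged and ungapped alignments at
shifted coordinates stay distinct rows — downstream cross-referencing is
window-based, so merging them would only discard provenance.

## Variant screen

A call is retained as a "unique variant" iff all of: FILTER is PASS; clone
genotype is heterozygous-alternative; parent genotype is
homozygous-reference; clone depth ≥ 10 reads; clone allele fraction ≥ 0.2.
The thresholds are read literally as *below excludes*, so DP = 10 and
AF = 0.2 are retained; both boundaries are unit-tested. Clone
homozygous-alternative calls are excluded under the genotype-pattern rule.
Excluded records are tallied under the first failing rule in the fixed
order filter → zygosity-unknown → genotype-pattern → depth →
allele-fraction. Multi-allelic records are decomposed per ALT allele before
screening, with zygosity evaluated per allele. The allele fraction comes
from the clone's `AF` FORMAT field when present, else from `AD`, else is
unknown (and screened out by the allele-fraction rule); unknown values are
never imputed. The same rules are applied to SNVs, MNVs and indels; indels
whose length change is ≥ 50 bp are reported as SV-class in summaries.

## Cross-referencing and the string search

Both detectors use a window of 200 bp flanking each side of the variant.
`crossref_sites` links a variant to every predicted site whose
protospacer+PAM span comes within the window (distance between closed
spans; overlap = 0). A variant within 2,000 bp of the intended target
interval is labeled `on_target`, otherwise `off_target_candidate`; the 2-kb
radius follows the practice of scrutinizing up to 2 kb around an edited
locus, and is configurable.

`string_search_screen` is intentionally cruder: it extracts each variant's
±200-bp flank and scans it, ungapped, for the plain protospacer and its
reverse complement with up to 4 substitutions, with **no PAM requirement**.
Dropping the PAM is what lets it recover edited loci whose guides were
designed against non-reference (e.g. patient-specific) sequence: the
PAM-anchored predictor can miss those, while the guide text itself is still
recognisably present near the edit. For ungapped loci within budget it is a
strict superset detector of the prediction route, which the suite asserts.

## CNV screen

Calls survive iff longer than 1 kb (strictly) and supported by a same-type
call from the second caller at reciprocal overlap
`min(ovl/len(A), ovl/len(B)) ≥ 0.5`. The 50 % reciprocal-overlap
concordance rule is the field convention for reconciling read-depth
callers; a `--single-caller` mode disables the concordance requirement for
manual-review workflows. Retained calls are categorised with fixed
precedence: `not_de_novo` (matches a parental call at the same overlap
rule) → `large_rare` (3–10 Mb, standing in for chromosome-scale
abnormalities; karyotype-level detection is out of scope) → `exonic`
(intersects a coding exon) → `other_de_novo`. Precedence had to be chosen
because the categories are not mutually exclusive by definition; parental
presence is checked first since a de novo label is meaningless otherwise.

## Cohort statistics

Per-clone means are plain arithmetic means, reported at full precision and
rounded only for display. Group comparisons use the pooled-variance
(equal-variance) two-sample Student's t-test with df = n₁ + n₂ − 2; the
equal-variance form is the one that reproduces the bundled cohort's
published p-values (0.003 for plasmid-vs-RNP delivery, 0.2536 for
Cas9-vs-Cas12a) from the per-clone event counts, and is appropriate for the
small, similarly dispersed groups involved. The two-sided p-value is
computed through the regularised incomplete beta function,
`P(T > t) = ½ I_{ν/(ν+t²)}(ν/2, ½)`, and verified against numerical
integration of the t density to 10⁻⁶ for df 1–60. Degenerate inputs are
defined rather than erroring: zero pooled variance with equal means gives
t = 0, p = 1; with unequal means, p = 0 with a warning.

The bundled cohort's unintended-event counts follow one convention: one
event per genome-wide WGS variant row, plus one event per clone with an
unintended on-target modification (a linked insertion+deletion at a single
locus counts once). Intended edits — silent recut-blocking variants and
deliberately inserted disease variants — are flagged `intended` in the
bundled table and never counted. This is the convention under which all
four published group means (5.0, 1.0, 1.83, 0.5 events/clone) are
simultaneously consistent with the per-clone tables. Recomputed mean
coverage is 41.38× where the source prints 41.3×, a rounding-level
discrepancy reported at full precision rather than asserted.

## Synthetic fixtures

The generator emulates the study design at test scale: an IID random genome
at 41 % GC (human-like), guide matches planted with an exactly realized
mismatch/bulge/PAM state, a two-sample Mutect2-style VCF whose records are
engineered to pass the screen or fail exactly one named rule, and
dual-caller CNV call sets covering every concordance/category branch.
Plants are spaced at least 2 × (guide length + window) apart so truth
records cannot cross-talk. All generators are pure functions of their seed.

What the fixtures do *not* model: sequencing error and read-level evidence
(no FASTQ/BAM), alignment artefacts, mosaicism/subclonality (allele
fractions are set, not sampled), linked haplotypes, and realistic genome
composition (repeats, segmental duplications) — so passing tests
demonstrate the correctness of the screening logic and search engine, not
performance on the error modes of real WGS data. Background sequence can
contain accidental near-matches to a planted guide; truth assertions at
planted loci are therefore subset assertions, with full-output correctness
pinned separately by the enumeration oracle.

Default problem sizes — 1-kb genomes for the 50-seed oracle-equivalence
sweep, a 40-kb contig for the end-to-end scenario, 20-nt guides — were
chosen so the exhaustive oracle remains exact while the full suite runs in
well under a minute; the engine itself is vectorized and handles megabase
contigs comfortably.

## Known limitations

* Off-target prediction is purely alignment-based; no cleavage-activity
  scoring (CFD/MIT), chromatin context, or per-tool PAM restrictions —
  profiles differ only in their (mismatch, bulge) budgets.
* Variant calling and CNV calling are upstream: the package consumes their
  VCF/BED output and never re-examines reads.
* Attribution of linked variants to editing versus culture adaptation is
  not modelled; the cross-reference reports proximity, not causality.
* The t-test machinery assumes two groups; with more delivery methods or
  Cas systems an ANOVA-style extension would be needed.
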