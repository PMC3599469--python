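# Methods

## Evidence model

All filters and evaluations share one counting primitive: per sample and
locus, the *pileup evidence* `(depth, alt_count, alt_count_long_mate,
alt_count_short_mate)`. An observation qualifies when its read is mapped,
primary, non-supplementary, passes QC, and meets the configured gates
(minimum base quality, minimum mapping quality; duplicate-flagged reads are
excluded unless requested). Defaults are maximally permissive — base and
mapping quality 0 — because the filters are designed around the idea that
evidence "in any read" of a comparator is informative; duplicates are
excluded by default because duplicate removal is assumed upstream and a
retained flag is treated as authoritative. A read whose alignment places a
deletion or reference skip across the locus contributes a GAP: GAPs never
count as alt support and are excluded from depth.

Coordinates are 1-based throughout (VCF convention); BED input is converted
from its 0-based half-open form exactly once, at parse time.

### Mate classes

Imbalanced paired-end chemistries produce a long and a short mate (50 and
35 bases by default). Two classification modes:

* `by-length` (default): a paired read strictly shorter than the cutoff is
  short-mate. With no explicit cutoff, the cutoff is the longest qualifying
  read length observed at the locus — in a 50/35 chemistry the 35-base mate
  is short, and on a balanced chemistry no read is ever short, making the
  paired-end filter a no-op there without any configuration.
* `by-ordinal`: the configured mate (first/second of pair) is short,
  for chemistries where the short mate's identity is fixed.

Unpaired reads are long-mate in both modes.

## Rare-and-true filter

Parameters: read threshold `t ≥ 1` (comparator is variant-like when
`alt_count ≥ t`) and percent threshold `p ∈ (0, 100]` (candidate discarded
when the variant-like percentage is ≥ `p`; "kept below the threshold"
means the boundary case discards). Study settings: `t = 1`, `p = 30`, 8
comparators. Decisions:

* The denominator is the full comparator panel, including files with zero
  coverage at the locus — the panel size, not the covered count, is the
  unit the thresholds were calibrated against. A covered-only denominator
  would be stricter at poorly covered loci; callers wanting it can filter
  the panel per locus themselves.
* The threshold comparison is exact rational arithmetic
  (`100·k/N ≥ p` as fractions), so grid boundaries like 3/8 vs 30% never
  depend on floating-point rounding.
* Keeping relatives out of the comparator panel is the caller's duty; the
  tool verifies sample-id uniqueness and warns when the test sample id
  appears in the panel.
* Binned variants are written to a sibling VCF with a
  `SIEVE_BIN=comparator-signature` reason tag, with per-comparator counts
  in `SIEVE_CMP` and the percentage in `SIEVE_CMP_PCT`.

The filter deliberately does not classify discarded candidates into "common
variant" vs "artefact": under a rare-variant model both are removed, and
their comparator signatures overlap by construction.

## Paired-end bias filter

A candidate is binned iff it has ≥ 1 alt-supporting read in the test
sample's BAM and zero long-mate alt support. One alt-supporting long-mate
read suffices to keep a variant (a single balanced observation refutes
"evident only in short reads"); requiring more would trade sensitivity for
little specificity at typical depths. Candidates with no observed alt
support at all are kept and flagged `no-support-observed` — they are not
evidence of short-mate bias, but the flag makes the (unusual) situation
auditable. This filter consults only the test sample's alignments, never
the comparators.

## Family annotation

For each variant and each relative's BAM: alt/depth counts plus a shared
flag at `alt_count ≥ t` (default `t = 1`, i.e. any read). Written as VCF
INFO keys `SIEVE_FAM` (per-relative `sample:alt/depth`, lexicographic by
sample id) and `SIEVE_FAM_N` (number of relatives with evidence), declared
in the header. Annotation is idempotent (re-running overwrites the keys)
and never changes the variant set. No inheritance-model logic is applied:
the annotation informs shortlisting under whatever model the analyst holds,
it does not automate it.

## Evaluation procedures

**O/E shared SNVs.** For a relative pair with `n_a`, `n_b` candidate
variants of which `s` are shared (exact `(chrom, pos, ref, alt)` identity),
`expected = φ · (n_a + n_b)/2` and `O/E = s / expected`, with kinship
`φ = 0.125` for first cousins. The mean-of-counts aggregation is one
reasonable symmetric choice; `min`/`max` are exposed as options and the
ratio is scale-equivariant regardless. Artefacts recur across samples, so
they inflate `s` roughly in proportion to their number rather than to
`φ · n`; this is what makes O/E ≫ 1 diagnostic of contamination and O/E ≈ 1
diagnostic of a clean list.

**Known-variant sensitivity projection.** Per known SNV, across a panel of
alignment files: files with alt frequency ≥ 9% among qualifying reads
(depth > 0) are true carriers and excluded; if ≥ 30% of the remaining files
show the allele in any read, the comparator filter would have removed the
variant — a projected false negative. Zero-depth files cannot be carriers
but stay in the remaining-file denominator by default (they are still
examined files; a covered-only denominator is available). Carrier frequency
is computed on gate-qualifying depth, with the same permissive default
gates as the filters, so the projection and the filter count reads
identically. SNVs uncovered in every file, or whose files are all carriers,
are skipped with a warning and excluded from the aggregate.

## Synthetic cohorts

The generator emulates the statistical structure the filters exploit, not
sequencing realism. Reads are ungapped perfect-match alignments (uniform
fragment starts, fixed fragment length 160, mapping quality 60, base
quality 40) over a uniform-random reference, so pileup counting — not
alignment — is what the tests exercise; an optional deletion-bearing read
class (`deletion_read_fraction`) exercises the GAP rule. Defaults: 10
samples, one cousin pair, 8 kb reference, 30× coverage, 50/35-base mates.

Site classes and defaults:

* `true_rare` / `shared_family` — heterozygous, target alt fraction 0.5.
  Each cousin carries 48 rare variants; the shared count is drawn
  `Binomial(48, 0.125)` per pair, the rest are private, so each cousin's
  variant count is fixed while sharing follows kinship. Other samples get 6
  private rare variants each. Genuine variants are planted with at least
  one long-mate alt read whenever one covers the site (mate-balanced
  support).
* `common` — 10 sites, alt fraction 0.4–0.6, prevalence drawn from
  (0.5, 0.9). The prevalence range is a contract: the carrier count is
  clamped to `[⌈0.5·n⌉, ⌊0.9·n⌋]`. At 50% minimum prevalence a common
  variant is visible to ≥ 3 members of any 8-of-10 comparator panel, which
  is what makes the class structurally recoverable by the filter at the
  30% setting — "common" here means common in the cohort.
* `artefact_mapping` — 20 sites, per-site prevalence drawn from (0.3, 0.9)
  across samples, per-carrier alt fraction 0.08–0.4. Fractions are capped
  below homozygosity (recurrent artefact signals are never
  homozygous-like); every carrier shows at least one alt read. Artefacts
  whose prevalence lands below 3 of the 8 comparators are *not* expected to
  be filtered — they are the residual noise that keeps post-filter O/E
  slightly above 1.
* `artefact_pe` — 8 sites whose alt bases are confined to short-mate reads
  (fraction 0.15–0.4). On a balanced-chemistry cohort these sites are
  planted as unrestricted mapping artefacts instead, since no short mates
  exist.

Planting achieves the nearest realizable fraction: `round(f · depth)` reads
(half away from zero), capped by the eligible pool and the class's maximum
fraction. Candidate VCFs list every planted site with ≥ 1 alt read in that
sample, emulating permissive upstream calling; sequencing errors (default
rate 0) are applied after planting, so the truth table is exact only at
error rate 0. All randomness is drawn from substreams keyed by
`(seed, stream, site, sample)`, so a seed reproduces the cohort byte for
byte and adding samples or sites does not reshuffle earlier ones. Site
positions are drawn uniformly (margin 60 bases from the reference ends) and
redrawn until every carrier has ≥ 4 covering reads (and a short-mate /
long-mate read where the class needs one); relocations are logged.

What the generator does **not** model: alignment ambiguity (the actual
cause of recurrent artefacts), colour-space or context-dependent error
profiles, GC/capture bias, indels, CRAM. Passing tests therefore
demonstrate that the filters implement their decision rules exactly and
recover the planted signal classes; they do not measure performance on real
exomes, where artefact prevalence and frequency spectra are unknown.

## Numerical and interface choices

* VCF records are decomposed per alt allele and filtered independently;
  surviving alleles are re-emitted as separate records. The original
  ID/QUAL/FILTER/INFO columns are carried verbatim (Number=A INFO fields
  are not re-sliced on decomposition — the suite's own annotations are the
  authoritative additions).
* Exclusion tables match `(chrom, pos, alt)` when the table supplies
  alleles and `(chrom, pos)` otherwise, since dbSNP-style exports vary.
* The two filters are independent per-variant predicates, so applying them
  in either order yields the same kept set (property-tested); the CLI
  examples use paired-end bias first.
* Filter outputs contain no timestamps, so reruns are byte-identical; run
  manifests (which do carry a timestamp) record parameters, input checksums
  and in/kept/binned counts.

## Problem sizes

Tests and the acceptance script run on cohorts of 6–20 kb references at
15–30× coverage with 10–12 samples, and 10–20 replicate cohorts for the
O/E summaries — sizes chosen so the full pipeline (generation, filtering,
evaluation) is exercised end-to-end in well under a minute per scenario
while leaving the binomial sampling error of the O/E mean (≈ 0.08–0.12)
small against the qualitative effects being checked (pre-filter O/E ≳ 2,
post-filter ≈ 1).

## Known limitations

* SNVs only: indels, MNVs and symbolic alleles are skipped (and counted).
* Empirically fixed thresholds; no coverage- or context-adaptive
  (Bayesian) weighting of comparator evidence.
* The comparator filter assumes comparators share chemistry and pipeline
  with the test sample; panels mixing platforms weaken the signature.
* The paired-end filter is meaningful only for imbalanced chemistries; on
  balanced data it is an intentional no-op.
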