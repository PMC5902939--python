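# Methods

## The problem

Variant calling from exome sequencing is a pipeline choice: a read aligner
(BWA-MEM, NovoAlign, ...) followed by a genotyping strategy (multi-sample
joint genotyping or per-sample single-sample genotyping).  Different
pipelines disagree, and the disagreement is not random noise: each single
pipeline systematically misses real variants that another configuration
recovers ("rescues"), the missed fraction grows with cohort size, and the
missed variants are disproportionately rare — exactly the variants large
sequencing studies exist to find.  `varrescue` implements the comparison
and characterization machinery for this problem: call-set algebra over
variant keys, a quality-metric battery for any variant group, the standard
exome sample-QC cascade, a functional-annotation layer, and a generative
simulator that reproduces the statistical structure of such cohorts so the
whole analysis can be exercised and validated without access-controlled
data.

## Variant identity and filtering

All cross-pipeline matching uses the exact normalized key
`(chrom, pos, ref, alt)` with 1-based positions and `chr`-prefix-insensitive
chromosome labels.  No positional fuzziness or allele renormalization is
applied: every compared call-set is restricted to bi-allelic SNVs on the
same reference, for which exact matching is correct.

The inclusion cascade retains a record iff:

1. FILTER is exactly `PASS` (anything else, including `.`, fails);
2. the ALT column named exactly one alternate allele (multi-allelic sites
   are dropped, not split into bi-allelic rows) and ref/alt are single,
   distinct A/C/G/T bases;
3. (joint-genotyping mode only) the fraction of roster samples with a
   called genotype is **at least** `min_call_rate` (default 0.90,
   inclusive).  In single-sample mode no call-rate filter is applied, since
   a no-call and a homozygous-reference call are indistinguishable there.

A genotype is "called" iff both alleles are non-missing; half-calls count
as missing.  The call-rate filter is applied per call-set before
comparison; a flag disables it for sensitivity analyses.

## Set algebra, subsampling, rescue categories

`compare` reports unique/shared/union counts and percentages for a pair of
call-sets; `union_merge` produces one record per union key with a per-key
provenance map (genotypes carried per source, never reconciled).
`subsample_experiment` mirrors the repeated-subsampling design: at each
cohort size below the largest, five subsets are drawn uniformly without
replacement and the per-size mean/SD of the overlap percentages reported;
the largest size is drawn once.  Every (size, replicate) cell derives its
own sub-seed deterministically from the master seed, so cells are
individually re-runnable.

`rescue_sets` classifies every union key of up to four call-sets (default
joint, alternate-aligner joint, and one or two single-sample sets):
`shared_all`, `default_only` (not a rescue), `rescued_by_aligner` (absent
from default, in the alternate joint set only), `rescued_by_genotyping`
(absent from both joint sets, in a single-sample set), `rescued_by_both`
(absent from default, in both kinds of alternative), `other`.  The
categories partition the union; full presence flags are emitted so users
can re-cut with different precedence.

## The quality-metric battery

For any variant group (e.g. the unique/shared groups of a comparison):

* **BAP** (B-allele proportion): per carrier genotype,
  `alt_reads / (ref_reads + alt_reads)` from AD; pooled across the group,
  not averaged per variant first, matching how the pooled distributions are
  conventionally plotted.  Diploid het/hom calls center BAP at 0.5 and 1.
* **BAF** (B-allele frequency): alternate-allele count over called
  genotypes, divided by `2 x n_called`; missing genotypes leave the
  denominator.  The reporting histogram has an explicit first bin at
  **<= 0.5% inclusive** (its upper edge one ulp above 0.005 so an exact
  0.005 lands inside); the scalar `frac_rare_baf` is computed from raw
  values with `<=`.  In single-sample mode BAF is not computed and the
  carrier-count histogram stands in.
* **Carrier count**: samples with >= 1 alternate allele; count 1 defines a
  singleton; binned `{1, 2-4, >= 5, ...}`.
* **GQ / DP**: pooled over carrier genotypes with the field present.
  Defaults: GQ bins of width 5 on [0, 100]; DP log-spaced on [1, 1024];
  BAP 20 equal bins on [0, 1]; all configurable.
* **Flanking GC**: fraction of G/C among up to `window` bases on **each**
  side of the position (variant base excluded, N bases excluded from both
  numerator and denominator, truncated at chromosome ends).  "Flanking
  100 bases" is ambiguous between 100 total and 100 per side; the default
  is `window=100` per side and the parameter is exposed.
* **Region overlap**: each variant is assigned to exactly one of
  LCR / SDR / other using half-open BED semantics after 1-based/0-based
  conversion; LCR takes precedence when region sets overlap (the published
  categories are reported as disjoint without a stated precedence).
* **Ti/Tv**: transitions are A<->G and C<->T; the ratio is flagged
  undefined (counts still returned) when there are no transversions.
* **Tiers and known/novel** come from the annotation layer below.

Every histogram conserves its input count (checked as an invariant).

## Sample QC

The cascade evaluates every criterion for every sample (no
short-circuiting), so per-criterion failure counts can sum to more than the
number of removed samples.  Defaults: coverage >= 90% of target at 10x AND
>= 30% at 40x; call rate >= 0.95; Ti/Tv >= 2.8 (all inclusive,
"at least" semantics); contamination fails only when FREEMIX is **strictly**
greater than 0.02; sex check fails a reported male with F < 0.7 and a
reported female with F > 0.3; APOE metadata mismatch fails; cohort-level
relatedness/ancestry/batch flags fail when set.  Missing metrics make a
criterion indeterminate (sample retained on that criterion, tallied
separately) unless strict mode is on; unknown reported sex is likewise
indeterminate — conservative retention.

The sex-check statistic is the method-of-moments inbreeding coefficient
over X-chromosome sites, `F = (O_hom - E_hom) / (m - E_hom)` with
`E_hom = sum_i (1 - 2 p_i (1 - p_i))`: hemizygous males appear fully
homozygous on X (F near 1), females center near 0.  Callers should exclude
pseudo-autosomal coordinates; no PAR table is built in.  Per-sample Ti/Tv,
when computed here, uses the sample's non-reference PASS calls.

## Annotation tiers, known/novel, curated audit

Tier 1: start/stop-codon disruption or splicing (`stopgain`, `stoploss`,
`startloss`, `splicing`, plus common synonyms); Tier 2: non-synonymous
coding changes; Tier 3: everything else.  The highest tier among a
variant's terms wins; unknown terms warn and fall to Tier 3 (strict mode
errors); the mapping is user-extensible.  "Known" means the exact key is
present in any configured reference key list (dbSNP, ESP, ClinVar, 1000G,
ExAC, Kaviar, HRC, ...); novel variants with CADD PHRED >= 20 (inclusive)
are flagged as likely-deleterious novelties.

The package ships a curated 13-row table of previously published
pathogenic/protective coding variants in the autosomal-dominant early-onset
Alzheimer's genes (APP, PSEN1, PSEN2), with each variant's external
(gnomAD non-Finnish European) allele frequency and whether a default
single-pipeline analysis detected it.  `audit_curated_table` reports
detected/undetected counts, a per-gene breakdown, and the undetected
percentage rounded half-up to a whole percent.

## The generative simulator

The simulator produces every input the analysis consumes.  Design choices:

* **Allele-frequency spectrum**: a singleton class (probability 0.45, one
  heterozygous carrier placed in exactly one sample) plus a Beta(0.2, 1.2)
  alternate-allele frequency for the rest, clipped to (0, 0.5].  The Beta is
  deliberately U-shaped like a neutral site-frequency spectrum (density
  ~ 1/x near zero with a persistent common component).  This shape matters:
  a purely-rare unimodal tail concentrates mass at intermediate
  frequencies whose carriers move *out* of the dropout-eligible range as
  subsets grow, destroying the size-dependent divergence; with the
  U-shape, the discovered set at any subset size is a stable common core
  plus a rare margin that grows roughly linearly with n, which is what
  produces the observed monotone overlap decline.
* **Genotypes**: independent Hardy-Weinberg draws per sample at the drawn
  frequency (no linkage disequilibrium).
* **Reference and regions**: chromosomes tiled into 1 kb blocks; LCR/SDR
  blocks allocated globally at target fractions (defaults 0.5% LCR, 6%
  SDR) and bases drawn i.i.d. at per-class GC (0.30 LCR / 0.48 SDR / 0.45
  other).  Alternate alleles are transitions with probability 0.75
  (exome-like Ti/Tv of 3).
* **Aligner model**: per-region-class detection sensitivity.  The default
  pair gives aligner A (default-like) SDR sensitivity 0.88 vs aligner B
  0.96, with A slightly better elsewhere (0.997 vs 0.995) — aligners differ
  mainly where read mapping is ambiguous, and each contributes some unique
  calls.
* **Joint-genotyping dropout**: a detected variant with subset carrier
  count k is missed with probability `q_k`; defaults (0.3, 0.15, 0.07,
  0.03), zero beyond.  This is the minimal stand-in for the real
  mechanism — with thousands of samples genotyped jointly, the few reads
  supporting a private allele can be judged statistically insignificant —
  without simulating reads.  No quantitative dropout rates are published
  to calibrate against; the defaults are illustrative and reproduce the
  qualitative trends.
* **Single-sample mode**: each carrier's site-call retained independently
  (default probability 0.995); the variant is emitted iff one survives;
  non-carriers are no-calls.
* **Per-call noise** (carrier genotypes): DP ~ negative binomial (mean 40,
  shape 8, floor 1); AD alt reads ~ Binomial(DP, 0.5) for hets,
  Binomial(DP, 0.98) for homozygotes; GQ = min(99, 3 x DP).  Simple,
  documented, replaceable.  Hom-ref calls in joint mode carry genotypes
  but no per-call stats.  A configurable fraction of true calls (default
  1%) is mislabeled non-PASS to exercise the PASS filter.
* **Seeding**: one master seed, fanned out through named substreams
  (reference / cohort / per-pipeline / per-subset) via `SeedSequence`, so
  bundles and experiments are bit-reproducible and any cell can be re-run
  alone.

### What the simulator does and does not emulate

It emulates the *statistical* structure relevant to this analysis: the
rare-skewed spectrum, region-dependent aligner dropout, carrier-count-
dependent joint-genotyping loss, and plausible GQ/DP/AD marginals.  It does
not model reads, alignment, linkage disequilibrium, indels, multi-allelic
sites, batch effects, or population structure.  Passing tests therefore
demonstrate that the analysis machinery is correct and recovers generative
parameters — not that any particular real cohort has these parameter
values.

## Problem sizes and numerical choices

Synthetic validation runs use cohorts of 500 samples x 5000 variants over
eight 250 kb chromosomes (recovery checks pool 20 seeded cohorts;
subsampling uses sizes 50/100/200/500 with 5 replicates; the end-to-end
bundle uses 100 samples x 1500 variants) — sizes at which binomial standard
errors are small enough for 3-SE parameter-recovery checks while a full run
completes in minutes on one core.  Ties and degenerate inputs are handled
explicitly: empty unions, empty groups, and zero-called sites raise rather
than return NaN; an all-transition group returns an undefined Ti/Tv ratio
with counts; percentages are reported from exact integer counts.  JSON
reports are written with sorted keys and embed the config hash and master
seed, making byte-level determinism a testable property.

## Known limitations

* Genotype-level concordance is out of scope: pipelines are compared on
  variant *sites*, not on per-sample genotype agreement.
* The rescue vocabulary assumes at most two aligners and two genotyping
  modes (the 2x2 design); `union_merge` accepts N call-sets, but the
  category labels do not generalize beyond the 2x2.
* The simulator's dropout parameters are qualitative stand-ins; absolute
  rescued-variant percentages from synthetic runs should not be read as
  predictions for any real cohort.
* Only plain-text or gzip VCF/BED/FASTA are supported (no bgzip/tabix),
  and only diploid GT semantics ("|" treated like "/").
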