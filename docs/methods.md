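# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `autozyg`.  Coordinates are 0-based half-open
everywhere inside the package; VCF and PLINK MAP positions are converted
at the I/O boundary.

## Run-of-homozygosity detection

Commercial and academic ROH callers share the same scanning-window
scheme, and `autozyg` implements it explicitly so that it can be
verified against brute force:

* a window of `window_size` (default 50) consecutive markers is
  *homozygous* when it contains at most `max_het_in_run` (1)
  heterozygous and at most `max_missing_in_run` (5) missing calls;
* each marker's *vote* is the fraction of windows covering it (clipped
  to the chromosome) that are homozygous; the marker is in a run when
  the vote exceeds `window_vote_threshold` (0.05);
* maximal stretches of in-run markers are merged when separated by at
  most `window_size` markers and no positional gap above `max_gap`
  (100 kb).  Two genotyping errors inside one window span veto every
  window covering the markers between them; the resulting break is an
  artifact of window geometry, not evidence of heterozygous background,
  so bridging it is the statistically correct behaviour.  Genuine
  heterozygous background between two autozygous segments spans
  hundreds of markers at any realistic marker density and is never
  bridged;
* stretches are split at inter-marker gaps above `max_gap`, trimmed at
  both ends to homozygous non-missing calls, and reported when they
  have ≥ `min_snps` (50) markers, length ≥ `min_length` (1 Mb), and
  mean spacing ≤ `min_density` (50 kb/marker).

The het/missing allowances are deliberately *per window*, not per run:
a run spanning thousands of markers legitimately absorbs one miscalled
het per ~50-marker stretch, while a total-per-run budget fragments
every multi-megabase run at realistic (≈0.2–0.5%) genotype error rates.
The whole definition is constructive, so the test suite checks the
vectorised implementation against an independent marker-by-marker
re-implementation on a thousand random panels, exactly.

Reported boundaries are the first/last marker of the run; against
implanted ground truth they wander by a few marker spacings (the
homozygous tail of the flanking background), which bounds attainable
boundary accuracy at roughly 2–5 kb for a 1 kb marker spacing.

### Subject selection

Samples with at least one ROH longer than `long_threshold` (4 Mb,
strictly greater) form the candidate pool; of these, samples whose
long-ROH count strictly exceeds the pool's third quartile (linear
interpolation, the numpy default) are selected.  The strict inequality
makes ties at the quartile reproducible: either all excluded or all
included.  Summaries use the interpolated median (mean of the middle
two) for segment lengths and count a gene as "within ROHs" on ≥ 1 bp
overlap.

## Variant tiering

The filtration cascade is a pure conjunction of per-variant predicates,
so tier assignment is order-independent by construction; the exclusion
reason reports the first unmet requirement in a canonical order and the
reason tally always equals the number of variants that did not reach
the LFF tier.

Thresholds (all configurable via `TierParams`):

| parameter | default | meaning |
|---|---|---|
| `max_af` | 0.05 | max reported database AF for LFF |
| `min_roh` | 1 Mb | minimum containing-run length for LFF (≥) |
| `damaging_min_votes` | 2 of 3 | predictor consensus for LFF-D |
| `sift_damaging` | < 0.05 | SIFT damaging call |
| `pp2_damaging` | ≥ 0.957 | PolyPhen-2 HDIV probably-damaging call |
| `mt_damaging` | ≥ 0.5 | MutationTaster disease-causing call |
| `best_min_roh` | 3 Mb | containing-run length for best candidates (strict >) |
| `rare_af` | 1e-4 | "extremely rare" cut-off when not novel |
| `fpkm_min` | 1 | brain-expression flag (strict >) |

Decisions worth stating explicitly:

* A database that does not report a variant is *absent*, which is
  distinct from a reported frequency of 0; "novel" means absent from
  all three databases.  The frequency filter uses the maximum across
  reported values.
* "Never reported in homozygosity" treats an absent homozygote count as
  0; databases differ in whether they report the field at all.
* The 2-of-3 damaging consensus is required rather than 3-of-3 because
  genuinely damaging alleles are routinely tolerated by exactly one
  predictor; the worked examples in the test suite include such a case.
* The functional consequence set is missense, stop gain/loss, start
  loss, canonical splice site, frameshift and in-frame indel.
  phyloP conservation is carried and reported but not filtered on.
* Brain expression is a flag orthogonal to the main chain (damaging
  status is assessed on all LFF variants, expressed or not).
* Cohort tables count per-sample calls per row and *distinct* variants
  (by chrom/pos/ref/alt) and genes in the `All` row, so a variant seen
  in two samples counts once there.
* Ti/Tv is computed over SNVs only, transitions (A↔G, C↔T) over
  transversions, and is undefined (reported absent, with a warning)
  without transversions.

## Enrichment statistics

`permutation_overlap_test` draws `n_perm` (default 9,999) uniform
size-`|query|` samples without replacement from a background universe
and reports the add-one empirical p-value
`(n_as_extreme + 1)/(n_perm + 1)`, which is never 0 and is
super-uniform under the null.  When `C(|background|, |query|) ≤ 10,000`
the test enumerates every draw instead and the p-value is exact (no
add-one).  The default background for LFF queries is the set of genes
inside the selected samples' ROHs, which makes the null density-aware:
a hit is only surprising relative to what any ROH-resident gene list
would achieve.  Because the overlap statistic is integer-valued and
heavily tied, the null distribution of the p-value is discrete; the
calibration tests therefore check super-uniformity at fixed levels and
agreement (two-sample KS) with an independently constructed analytic
null (hypergeometric overlap + binomial Monte-Carlo layer) rather than
a one-sample KS against a continuous uniform, which would reject for
any tied statistic.

`interval_enrichment_test` relocates each query interval uniformly
within its chromosome, preserving length and resampling (up to 200
attempts) until the relocated interval covers a gene count within ±20%
of the original, matching the null on local gene density; the statistic
is the number of intervals hitting ≥ 1 target gene.  Gene lookup
assumes non-overlapping gene intervals per chromosome (true of the
synthetic gene maps; dense real annotations should be flattened first).
The multiple-testing treatment across sets is Benjamini–Hochberg, not
a two-stage bootstrap.

`hypergeometric_ora` computes the upper-tail hypergeometric p on the
2×2 table within the background and BH q-values across sets; sets with
fewer than 2 query hits are flagged rather than dropped.  Gene symbols
are matched by uppercased exact identity; alias resolution is out of
scope.

## Synthetic data generator

The generator emulates the observable structure of an array-genotyped,
exome-sequenced case series with recent-inbreeding subjects:

* **Marker map**: one marker per grid cell with uniform jitter, so
  counts are exact (`round(length × density)`) and positions strictly
  increasing; allele frequencies Beta(3, 3), a common-allele-weighted
  spectrum resembling array ascertainment.  Default density is
  1 marker/kb over four 40 Mb chromosomes — a desk-scale genome chosen
  so the full cohort simulates in seconds; density is a free parameter,
  not a claim about any particular array.
* **Cohort**: 180 samples; 15% are "inbred" and receive
  `max(1, Poisson(5))` autozygous segments with Exponential(mean 8 Mb)
  lengths, placed without overlap and with ≥ 500 kb separation (so
  segments are never merged by the detector), truncated at chromosome
  ends.  Background genotypes are Binomial(2, p) per marker
  (Hardy–Weinberg); inside segments the sample is homozygous for an
  allele drawn by its frequency.  Genotype error renders truly
  homozygous in-segment calls het (default 0.002); missingness (0.002)
  applies to every call.
* **Exome variants**: Poisson-planted at 10/Mb inside segments and
  2/Mb outside, with intended tier drawn 90/6/4% for
  non-candidate/LFF/LFF-D, plus one explicit best candidate per inbred
  sample with a ≥ 3.5 Mb segment.  Attributes (consequence, three
  database AFs and homozygote counts, SIFT/PP2/MT scores, brain FPKM)
  are realised to satisfy — or decisively violate — the tier
  definitions: non-candidates are synonymous, common (AF ≥ 0.06) or
  heterozygous; damaging variants get each predictor damaging with
  probability 0.9 subject to ≥ 2 votes; rare frequencies are
  log-uniform on [1e-6, 1e-4] and "novel" is absent from all three
  databases.  Candidate tiers are planted only ≥ 10 kb from segment
  edges and only in segments with margin over the 1 Mb / 3 Mb cut-offs
  (1.2 / 3.5 Mb), because detected boundaries wander a few marker
  spacings; without the margin, exact truth-tier recovery would be
  broken by boundary noise rather than filtration logic.  Transitions
  are drawn at 71.5%, giving an exome-like Ti/Tv ≈ 2.5.
* **Gene maps and sets**: non-overlapping genes tiled at 1/150 kb with
  log-normal lengths; gene sets of a requested size with
  `ceil(enrichment × |query|)` forced query members.

Determinism: every stage derives its RNG from (seed, stage constant),
so a fixed seed and config reproduce byte-identical outputs, and stages
re-run standalone reproduce the pipeline's artifacts.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: linkage disequilibrium and
the short background ROHs it produces in outbred genomes; pedigree- or
coalescent-accurate segment length/count distributions; allele-
frequency ascertainment of any specific array; read-level error
processes (the genotype error model is a symmetric per-call flip); and
correlated annotation errors across databases.

## Problem sizes

Default test and acceptance runs use the 180-sample, 160k-marker
cohort for recovery checks (~64k planted variants), 1,000 random
≤ 200-marker panels for oracle equivalence, 1,000 null replicates at
999 permutations for calibration, 500 replicates for FDR control and
100–200 replicates at 2,000–10,000 permutations for power; the full
suite runs in well under a minute per statistical block on one CPU.

## Known limitations

* ROH boundary resolution is limited to a few marker spacings; reported
  lengths inherit that uncertainty.
* The upper-quartile selection is sensitive to ties by design (strict
  inequality); cohorts where many subjects share the Q3 count select
  nobody from that tie group.
* The interval-relocation null preserves length and gene density but
  not chromosome-specific features (centromeres, segmental
  duplications).
* The blacklist and CNV inputs are consumed as given; no indel
  realignment or CNV calling is attempted.
* FROH (total ROH length / genome length) is exposed as a convenience
  field only; no inbreeding-coefficient inference is performed.
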