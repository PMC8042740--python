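# Methods

## Scope and data model

`pedcnv` analyses multi-sample structural-variant call-sets restricted to
copy-number variants (SVTYPE DEL/DUP).  All in-memory intervals are 1-based
and inclusive on both ends, the native convention of VCF and GTF; BED
output converts to 0-based half-open at serialization only.  A *site* is
one VCF record; an *event* is one non-reference genotype at one site in one
sample.  Genotypes are diploid and bi-allelic: `0/1` and `1/0` map to het,
`1/1` to hom-alt, `./.` to missing; multi-allelic SV records are rejected,
as the emulated caller stack (split/discordant-read calling with joint
re-genotyping) does not produce them.

For record length, SVLEN is authoritative when present (htslib recomputes
the record's end from SVLEN for symbolic alleles, so INFO/END cannot be
recovered independently of it); otherwise END defines it as
`END − POS + 1`.  The end coordinate is always `start + length − 1`, which
keeps length and interval arithmetic mutually consistent.  Per-sample depth
fold-changes are read from FORMAT tags (defaults `DHFFC`, variant depth
over flanking depth, and `DHBFC`, variant depth over depth in similar-GC
bins, matching the tags of the common depth-annotation tool); the tag names
are parameters.

## Filter cascade

Six rules run sequentially in a fixed order (carrier count, length,
quality, deletion depth support, duplication depth support, Alu window); a
site removed at a rule takes its remaining events with it, and the report
reconciles exactly in both units.  Choices the rules' prose leaves open:

* "Present in ≥ 31 of 32 individuals" means a non-reference genotype (het
  or hom-alt) — carrier status is the natural reading for a filter aimed at
  variants carried by the reference individual.
* The depth-support rules are *retention* rules: a deletion survives only
  if its carriers' `DHFFC` satisfies `< 0.7`, a duplication only if its
  carriers' `DHBFC` satisfies `> 1.3`.  Per-carrier values are aggregated
  to one site-level value by the **median over carriers** (robust and
  deterministic); `mean` and `all-carriers-must-pass` are available as a
  config choice.  A site lacking the annotation its type needs is removed
  and counted under that rule by default (configurable to keep).
* Length uses SVLEN when given, else `end − start + 1`; the Alu window
  [275, 325] is closed on both ends.
* An optional pre-cascade pruning step collapses sites whose start
  positions fall within 100 bp (transitively chained, per chromosome),
  keeping the highest-QUAL site; QUAL ties break to the leftmost start and
  then lexicographic id, a tie-break the upstream tooling leaves undefined.

## De novo calling and the mutation rate

A de novo call for trio T requires: proband het (hom-alt probands are
excluded), both parents hom-ref, and every other cohort member hom-ref —
except individuals whose sire or dam is the proband (the F1 allowance: a
true de novo in an F1 proband is transmitted to each of its own offspring
with probability 1/2).  Uniqueness is enforced across the *entire cohort*,
not just the trio.  Missing genotypes: a missing call in a trio member
skips the site for that trio under the default `strict` policy; the
`parent-missing-tolerant` policy treats a missing parent as compatible with
hom-ref.  Outside the trio a missing genotype never disqualifies a
candidate — absence of a call is not evidence of carriage.

The haploid per-generation rate is `mean(per-trio counts) / 2`.  The 95%
interval is `rate ± 1.96 · sd(counts)/√n / 2` with the sample (n−1)
standard deviation and the fixed normal critical value; the half-width
carries the same 1/2 haploid scaling as the mean — the only scaling under
which eight events over 14 trios reproduce the interval [0.12, 0.45], as
verified by exhaustive enumeration of all count multisets summing to eight
(there are 22; exactly one, {2, 1×6, 0×7}, rounds to those bounds).  The
lower bound is floored at zero, and the interval is undefined (an error)
for fewer than two trios.

## Paternal-age regression and power

The regression is ordinary least squares of per-trio de novo counts on sire
age at conception, with the two-sided t test (n − 2 df) on the slope.  A
flat response (zero count variance) is reported as slope 0, R² 0, p 1.

The power simulation asks whether the cohort's age spread could reveal a
positive age effect of a given strength.  A reference count table — in the
motivating analysis, de novo single-nucleotide counts, which do rise with
paternal age — is fit by OLS; each replicate redraws counts around the
fitted line (Gaussian with the fitted residual variance, or Poisson with
the fitted means floored at 10⁻⁶, since Poisson requires positive means and
fitted values can dip below zero at young ages), refits, and counts
replicates with a *significant positive* slope: two-sided p < α and slope
> 0 (a flag switches to the one-sided upper-tail test).  Gaussian draws are
deliberately not truncated at zero; refitting is unaffected.  Replicate
fitting is vectorised, so 10,000 replicates take well under a second.  The
pipeline, lacking the unpublished per-trio SNV tables, synthesises an
SNV-like reference (Poisson counts with mean `slope × age`, slope
configurable, default 1.5/yr; the acceptance script uses 5/yr to match the
magnitude of a strong single-nucleotide age effect).

## Overlap accounting

Features are genes, transcripts and exons from GTF (deduplicated by
identifier; alternative transcripts of a gene count independently), plus
strand-aware 10 kb windows up- and downstream of each gene as regulatory
proxies, truncated at chromosome boundaries.  Overlap requires ≥ 1 shared
base; there is no reciprocal-overlap minimum.  *Full* overlap means the
feature lies entirely within the CNV; *partial* means a non-empty,
non-containing intersection.  Three views are produced:

* region-centric: each feature counted once per CNV type, full taking
  precedence over partial when different CNVs hit it in different modes;
* CNV-centric: each CNV counted once per feature class, full if it fully
  contains at least one feature of the class;
* per-CNV averages, over all CNVs of a type and conditional on at least
  one overlap (conditioning per mode, with `all` = full + partial).

The asymmetry of the two "full" definitions (feature-in-CNV versus
CNV-contains-a-feature) is deliberate: it is the only pair of readings
under which region-centric and CNV-centric full counts can diverge in the
direction observed in practice, and it is pinned by tests against an
all-pairs brute-force scan.  The indexed implementation (an interval tree
per chromosome) is exactly equivalent to the quadratic scan on every tested
cohort.

## Ratio and distribution statistics

The 2×2 χ² uses the Yates continuity correction by default (correction
clamped at zero when |ad − bc| < n/2), with p from the upper χ²₁ tail —
the variant that reproduces both published exon-contrast statistics (20.82
and 41.344) from the published tables; a flag disables it.  The
exon-versus-call-set contrast compares exon-overlapping CNV counts against
the **full** call-set (overlapping rows, not disjoint ones), mirroring the
comparison as performed.  KS length comparisons exclude the [275, 325] bp
Alu window from both samples by default and use the asymptotic two-sample
p-value.  Term enrichment is a per-term two-sided Fisher exact test on
{overlapped, not} × {annotated, not} over the transcript universe with
Benjamini–Hochberg adjustment at FDR 0.01.  The polymorphic-versus-fixed
contrast takes the fixed gene loss/gain counts as a two-column input (the
cross-species gene-family inference that produces them is out of scope).

## Synthetic cohort generator

The generator's defaults are the study conditions of the motivating cohort:

* **Pedigree**: 32 individuals, 14 trios — three multigenerational
  families (a sire with three dams and three offspring, the eldest
  offspring siring a grandchild with an unrelated dam; 4 trios each) plus
  one simple two-trio family.  Three probands are F1 (also parents).  Sire
  ages at conception are uniform on 4–12 years, a spread skewed young
  relative to the species' lifespan.
* **Sites**: 8,515 pre-filter sites; 88% of segregating sites are
  deletions.  Lengths are log-normal per type (σ_log = 1.2, means set so
  the untruncated expectations are 3,161 bp for deletions and 6,990 bp for
  duplications), truncated by rejection to [40 bp, 100 kb].  The law is a
  modelling choice for the observed right skew; the truncation bounds are
  the observed minimum and the filter cap.
* **Genotypes**: founder allele frequencies uniform on (0, 0.5] (a
  placeholder — no frequency spectrum is published for these CNVs — and
  configurable), founders in Hardy–Weinberg proportions, descendants by
  Mendelian gamete draws.  Monomorphic segregating sites are redrawn, since
  every call-set site was a call in someone.
* **De novo events**: per-trio counts Poisson with mean 0.57 transmissions
  (haploid rate 0.285); each event het in its proband, hom-ref everywhere
  else, and transmitted to each of an F1 proband's offspring with
  probability 1/2.
* **Annotations**: QUAL uniform on [100, 2500] for clean sites; depth
  fold-changes Gaussian around genotype-determined means (non-carrier 1.0;
  het/hom deletion 0.5/0.05; het/hom duplication 1.5/2.0), truncated at 0,
  sd 0.1 by default.  The carrier means sit two default-noise sd inside the
  0.7/1.3 thresholds, so the depth rules have high but imperfect
  sensitivity and filter tests exercise both outcomes.
* **Artifacts**: injected at the pre-filter composition implied by the
  curated call-set's per-rule removals — 30.7% reference-individual sites
  (carried by ≥ 31 of 32), 5.4% oversize, 2.9% low-quality, 1.3%
  Alu-window.

What the generator does **not** emulate: linkage between sites, locus-
specific mutation hotspots (NAHR), genotyping error correlated with depth,
length-dependent discovery sensitivity, mobile-element insertions, and
breakpoint sequence.  Passing tests therefore demonstrate the correctness
of the accounting, calling and estimation machinery under the stated
statistical conditions, not robustness to every failure mode of real
sequencing data.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeds; a pipeline
run derives per-stage seeds by hashing the stage name with the global seed
(first four bytes of SHA-256, kept below 2³¹), so stages re-run in
isolation reproduce the full run bit for bit and manifests contain no
timestamps.  QUAL values read through htslib are rounded to three decimals
to undo float32 storage noise.  Ratio denominators of zero are flagged as
infinity rather than raised, except where a statistic is undefined (zero
χ² margins, single-trio intervals, empty KS samples), which raise.

Test problem sizes are chosen to keep the default suite fast while leaving
the estimators in their operating regime: conservation and recovery
properties run on cohorts of 200–1,000 sites, caller correctness on 100
seeded 200-site cohorts, overlap equivalence on 50 cohorts of up to 500
sites × 500 features, and power checks at 4,000–10,000 replicates.

## Known limitations

* The rate interval is a normal approximation on 14 trios of small Poisson
  counts; its true coverage under the generator's own conditions is about
  90–93% rather than the nominal 95%, dipping lowest (~90.5%) at a haploid
  rate of 1.0, where the coverage-recovery property sits exactly at its
  acceptance boundary.
* Per-rule removal counts on real data depend on the upstream caller stack
  and cannot be reproduced from a simulation; only the accounting
  identities are checkable.
* De novo validation by within-trio breakpoint sequence identity is not
  emulated; calls are genotype-logical only.
* Half-missing parental genotypes at candidate sites have no published
  treatment; both policies are exposed and `strict` is the default.
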