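# Methods

## The problem

Two bacterial genome assemblies from the same species almost always show
average nucleotide identity (ANI) well above the ~95% species boundary,
but "very high ANI" alone cannot separate three situations that matter
when tracking strains across body sites or time points:

* the two assemblies are the **same strain** (resequencing of one clone);
* they are **related strains** (recent common ancestor);
* they are **different strains** of the same species.

Even a genuinely identical strain, sequenced and assembled twice, does not
give ANI = 100%: subsampling of reads, coverage gaps and consensus errors
leave a characteristic deficit of a few hundredths of a percent, with
run-to-run spread. The method implemented here turns that deficit into a
reference distribution and asks whether an observed genome pair could be a
draw from it.

## The statistical procedure

For each strain with a deep read set, `n_replicates` (default 50)
subsamples of `n_pairs` (default 150,000) whole read pairs are drawn with
recorded seeds, each subsample is assembled, and the resulting assemblies
are compared in **disjoint consecutive pairs** — each assembly enters
exactly one comparison, avoiding pseudo-replication — yielding
`n_replicates/2` same-strain ANI values per strain. Per species, these
values are pooled across strains, a one-way ANOVA of ANI by strain is
reported (a significant strain effect indicates strain-level diversity is
represented in the pool; a warning is logged otherwise — the ANOVA never
gates anything), the pool is enlarged by a bootstrap with replacement
(default B = 10,000 draws), and a Gaussian KDE (Silverman bandwidth) is
fit for visualization.

An observed ANI between two genomes of that species is then given a
left-tail empirical P-value

    P = #{null values <= observed ANI} / n,

computed on the bootstrap sample by default (`p_from="ecdf"`); a
KDE-integrated tail is available behind `p_from="kde"`. The alternative is
one-sided: a truly different strain is an outlier on the left tail. Calls:
P < 0.05 → "different"; P >= 0.95 → "identical"; otherwise "related".
Ties follow the operational rule (exactly 0.95 is "identical", exactly
0.05 is "related"). Each species gets its own null; cross-species pairs
are refused. No multiple-testing correction is applied across pairs.

With a finite pool of n values the P-value is discrete — n+1 atoms — so
the nominal type-I rate at the 0.05 threshold is 1/(n+1), not exactly
0.05. At the default scheme (e.g. 11 strains × 25 pairs) this distinction
is negligible; at desk scale (20 pooled values) it is visible and the
validation studies account for it.

## Fragment ANI

The built-in estimator cuts the query into non-overlapping 3,000-bp
fragments (terminal remainder discarded), anchors each fragment to the
reference through shared 16-mers on both strands (anchor hits are taken
on a stride of 4 fragment k-mers; k-mers with more than 16 reference hits
are ignored as repeats), chains runs of anchors that share a diagonal
(small indels shift the alignment to a neighbouring diagonal, opening a
new run; runs with a single anchor are discarded as chance hits), and
scores ungapped percent identity over the chained spans, clipped to the
contig each span lands in. Fragments below 80% best identity are
unmapped; ANI is the mean identity of mapped fragments, and it is
reported as *missing* — never as 0% — when fewer than `min_mapped`
(default 10) fragments map. The symmetric summary is the arithmetic mean
of the two directional values. Tables from an external ANI tool (the
common 5-column tab-separated dialect) can be substituted anywhere
downstream.

Design choice: the estimator is deliberately ungapped after chaining.
The null-distribution machinery needs a fast identity statistic that is
*consistent* between null construction and observed pairs, not a
reimplementation of an external mapper's alignment stack. Accuracy on
substitution-only pairs is within 0.1 percentage points of the
mutation-log ground truth (validated continuously); the near-perfect
forward-strand shortcut (skip the reverse strand when forward identity is
already ≥ 99%) cannot change any result on real nucleotide sequence.

## Synthetic data and the assembly emulator

The generator provides: an i.i.d. ancestor at a chosen GC fraction
(default 0.42, typical of lactobacilli); derived strains with per-base
substitution and indel rates (indel lengths geometric with mean 3 —
unconstrained by the method, since ANI and SNP counting are dominated by
substitutions — and an exact replayable mutation log as ground truth);
2×150 bp paired reads with uniform fragment starts (insert 400 ± 40 bp)
and per-base substitution error (default 10⁻³, constant Q40 qualities);
and an **assembly emulator**.

The emulator does not assemble reads. It reproduces the two statistical
signatures of short-read assembly that the method depends on: contigs
break at coverage gaps, and rare consensus errors concentrate where the
evidence is thin. Per 150-bp window it draws an effective depth
d ~ Poisson(`mean_depth`); windows below `min_contig_depth` become gaps
that split contigs (contigs under 1,000 bp are then dropped, mirroring
the pipeline's contig filter), and every retained base is substituted
with the exact probability that a strict majority of d evidence reads
carry the same wrong base, each read wrong with `base_error_rate` (the
three wrong bases equiprobable; ties at even depth resolve to the correct
base). The defaults — `mean_depth` 8, `base_error_rate` 0.05 — are an
*abstraction*, chosen once so that same-strain emulated assembly pairs
have ANI slightly below 100% (≈ 99.95) with replicate-to-replicate spread
(sd ≈ 0.01–0.02), the regime real same-strain assembly pairs occupy. They
are not instrument parameters: real assemblies see deep but uneven and
partly correlated evidence, and the low effective depth stands in for the
error-prone tail. Consequences for interpretation: passing tests show the
*statistical machinery* is calibrated and powered under a realistic noise
magnitude; they do not certify any particular sequencer or assembler,
model GC-coverage bias, quality-score structure, misassembly, or
contamination.

Seeds: every operation takes an explicit seed; per-replicate and
per-strain seeds are derived from one master seed through a counter-based
`SeedSequence` stream (recorded in outputs), so entire studies are
bit-reproducible from a single integer.

Because the emulator works from the strain genome, the pipeline's
emulator backend needs each strain's genome alongside its reads; the read
subsampling still runs per replicate (it is the study design and is what
an external assembler backend consumes), but emulated assembly noise is
driven by the replicate seed rather than recomputed from read pileups —
a known simplification.

## Validation studies (desk scale)

Run by `tests/test_acceptance.py` and `scripts/acceptance.py`. Problem
sizes are the package's chosen desk scale: 100-kb genomes, 4 strains per
species at 0.5% mutual divergence, 30,000-pair read sets subsampled to
20,000 pairs, 10 replicates per strain (→ 20 pooled values per species);
ANI accuracy uses 200-kb substitution-only pairs.

* **Calibration.** Two measurements. (a) *Exchangeability*: an exact
  two-sample Kolmogorov–Smirnov test between one pool's 20 same-strain
  ANI values and 200 fresh same-strain ANIs from the same generative
  process (α = 0.01). This is the distribution-free form of "fresh
  same-strain pairs look like draws from the null": a one-sample KS test
  of 200 P-values that share a single 20-value pool would violate the
  test's independence assumption and reject almost always, purely because
  a 20-point empirical CDF sits ~0.2 away from its population CDF.
  (b) *Type-I rate*: 40 independently constructed pools × 5 fresh pairs
  each give 200 near-independent P-values; the fraction below 0.05 is
  required to lie in 0.05 ± 0.03 (the discrete-pool nominal value is
  1/21 ≈ 0.048 on the pool ECDF; the bootstrap-ECDF pipeline path is
  also reported, expected ≈ 0.07 because bootstrap jitter splits the
  atom that falls exactly on the threshold).
* **Power**: 200 genome pairs at 0.3% divergence must be called
  "different" ≥ 99% of the time (their ANI ≈ 99.66 lies ~20 null
  standard deviations below the null mean).
* **ANI accuracy**: |fragment ANI − Hamming identity from the mutation
  log| ≤ 0.1 percentage points at divergences 0, 0.1% and 0.5%.
* **Exact oracles**: the empirical P equals a brute-force count on 1,000
  random vectors; the ANOVA F equals the hand-computed 1.5 on the
  {1,2,3} vs {2,3,4} fixture; SNP counts equal an independent
  column-scanning oracle on 100 random alignments; CRISPR verdicts are
  invariant under strand flips and contig splits and symmetric in their
  arguments; the default scheme yields exactly 50 replicates, 25
  disjoint ANI pairs per strain, 10,000 bootstrap draws and 0.05/0.95
  thresholds.

## SNP counting convention

A column of a whole-genome multiple alignment is *considered* only when
every row carries an unambiguous base (no gap, no N); a considered column
is a SNP when ≥ 2 distinct bases occur. Percentages use considered
columns as the denominator — the only convention under which
"substitution" is well defined for all rows — and every report carries
the convention tag. Pairwise identity uses, per row pair, the columns
where both rows are unambiguous. Consequence: indel-rich alignments
report SNP percentages over a smaller denominator than "alignment
length"; comparisons with numbers computed under other denominators are
not meaningful.

## CRISPR array comparison

Arrays are ordered spacer lists per contig (from an external detector's
export; no de-novo detection). Equivalence must survive two assembly
artifacts: strand (one genome's array may be the reverse-complemented,
reversed list of the other's) and splitting across contigs. The verdict
is "identical" iff some ordering and per-array orientation of one
genome's arrays concatenates to some ordering/orientation of the other's
(exact spacer equality by default; `max_mismatch` allows per-spacer
tolerance). The order/orientation search is exhaustive up to 6 arrays per
genome and falls back to strand-canonical multiset comparison (with a
warning) beyond that. Shared/only-A/only-B spacer counts over
strand-canonicalized multisets are always reported, so partially
overlapping arrays are informative without forcing a verdict. Two genomes
with no arrays compare as "identical with zero spacers", flagged
distinctly as having no CRISPR system.

## Degenerate inputs and numerical choices

* ANI undefined (too few mapped fragments) propagates as missing, never
  as 0%; pairs with missing ANI are skipped with a warning.
* A pool whose values are all identical cannot support a KDE; the KDE is
  skipped with a warning (and `p_from="kde"` refuses to fit).
* ANOVA requires ≥ 2 strains with ≥ 2 values each and non-zero variance;
  otherwise it is reported as undefined, never invented.
* Bases outside {A,C,G,T,N} are mapped to N on input (count logged);
  N never matches anything in identity or SNP computations.
* KDE support grid spans the data range ± 5 bandwidths (2,048 points);
  its density integrates to 1 within 10⁻⁶.
* The contig-length filter removes strictly-shorter-than-1,000-bp
  contigs; a 1,000-bp contig is kept.

## Known limitations

* The emulator's noise is uncorrelated across replicates given the seed
  and contains no misassembly, chimerism or contamination; real
  same-strain nulls may be wider or skewed.
* The fragment estimator's chained-ungapped identity slightly penalizes
  fragments whose indels sit within one anchor stride of a fragment end.
* The pipeline assumes desk-scale data in memory; FASTQ streaming for
  arbitrarily large runs is out of scope.
* Classification reuses one ANI implementation for null and observed
  pairs (recorded in the report); mixing the built-in estimator's null
  with an external tool's observed values would bias P-values and is not
  prevented, only discouraged in the interfaces.
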