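# Methods

This note documents the models, conventions and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
problem sizes the analysis scripts and checks run at.

## Coordinates and strand conventions

All internal coordinates are 0-based half-open; GFF3 (1-based) is converted
at the reader boundary. "Transcript sense" is the strand the mRNA is read
from: for a minus-strand gene, downstream means smaller genomic coordinates
and inspected windows are reverse-complemented. A PAS coordinate is the
transcript-sense 3'-most qualifying base of its peak.

For the reverse 3'-Seq protocol the sequenced read is antisense to the
transcript. The extractor reports the transcript strand as the flip of the
alignment strand and takes the cleavage position at the read's 3'-most
aligned base (alignment start for reverse-strand alignments, end − 1
otherwise). This is a pinned convention — the protocol geometry admits more
than one defensible anchor — and the synthetic generator, extractor and all
downstream windows agree on it, which is what the filters require.

## Internal-priming filters

Oligo-dT can anneal to genomic A-stretches, producing reads whose "cleavage
site" abuts an A-rich region rather than a real poly(A) tail. Two screens
remove these:

- **Read level** — a read is dropped iff the 10 transcript-sense bases
  immediately 3' of its cleavage position (exclusive of it) contain ≥ 6
  consecutive A or ≥ 7 A total. Stated in read-mapping orientation this is
  the familiar "6 Ts in a row or 7 of 10 Ts directly upstream" rule; the
  transcript-sense formulation is strand-symmetric and directly testable.
- **Site level** — a called PAS is dropped iff the 15 bases downstream
  contain ≥ 6 consecutive A or ≥ 11 A total. Eleven is the smallest integer
  count of 15 that exceeds 70%. Windows truncated by a chromosome end are
  judged with a proportionally scaled count threshold and logged.

Both thresholds are read as "at least" (≥ 6, ≥ 7, ≥ 11); the boundary
behaviour is pinned by tests. Reads too close to a chromosome end to
evaluate are kept with a warning rather than silently dropped.

## Peak calling and gene assignment

A genomic base qualifies when it has a nonzero count in at least
⌈0.9 · L⌉ of the L pooled libraries *and* a cross-library mean count
strictly greater than 2. Maximal runs of qualifying bases on one strand form
peaks; a single non-qualifying base splits peaks (no minimum width or
inter-peak gap is enforced). Qualification uses a small epsilon guard so
that 0.9 · L at an exact multiple of ten is not pushed up by floating-point
error. Peaks are called on all libraries pooled (nuclear + total); both
fractions see the same catalog.

Assignment follows a fixed hierarchy — 3'UTR, 5 kb downstream of the gene,
exon, 5'UTR, intron — over same-strand overlapping features; ties within a
class break by larger overlap, then lexicographic gene id, making the result
independent of annotation row order. Reads are counted into every peak span
containing their cleavage position (spans from the caller are disjoint, so
this matters only for externally supplied overlapping annotations).

Usage is count over gene total per library; entries are *missing*, not zero,
when the gene has no reads in that library. A PAS is retained when its mean
usage is ≥ 5% in the nuclear or the total libraries (removal requires
failing both).

## Signal-site scan

The scan looks for exact, strand-aware matches of the 12 signal hexamers
(AATAAA, AATTAA, AAAAAA, AAAAAG, AATACA, AATAGA, AATATA, ACTAAA, AGTAAA,
CATAAA, GATAAA, TATAAA) in the 100 transcript-sense bases upstream of the
cleavage coordinate. A hit's offset is measured from the motif start to the
cleavage base; the presence flag asks for any hit starting 10–50 bases
upstream, both endpoints inclusive. The background rate draws random 40-base
windows uniformly from introns (intron chosen uniformly among those long
enough, then a uniform start) and scans them on the intron's transcript
sense. Rates between categories are compared with a two-sample
pooled-variance proportion z-test.

## Differential usage (Dirichlet-multinomial LRT)

Counts for one gene across samples are Dirichlet-multinomial with
α = α₀ · p. The null shares p across fractions; the alternative fits one p
per fraction; α₀ is shared within each model (whether the original
external implementation used per-fraction concentrations is unknowable; the
shared form is adopted and stated). Proportions are parametrized as softmax
logits with the last category pinned, α₀ on the log scale with bounds
[e⁻³, e¹⁶]; the upper bound is the multinomial limit. Optimization is
L-BFGS-B from pooled-proportion initialization, run from two starts (a
moderate concentration and the multinomial-limit bound) because the
likelihood is nearly flat in log α₀ once the data look multinomial; the
better optimum wins. The LRT is clipped at zero and referred to χ²(K−1).

Exact numeric agreement with any particular external differential-splicing
script is *not* a goal; the verified contracts are the likelihood itself
(checked against Pólya-urn enumeration for all K ≤ 3, N ≤ 4 cases to 1e-9),
null calibration (uniform p, 5% rejection at α = 0.05 over 500 simulated
null genes) and power with correct ΔPAU sign against planted decay.

ΔPAU is computed from raw usage means over non-missing samples, total minus
nuclear, so per-gene ΔPAU values sum to zero and a negative value means
nuclear-enriched. Labelling requires gene-level BH significance at 10% and
|ΔPAU| > 0.2; nuclear-enriched sites with mean total usage ≤ 1% are
additionally flagged as near-absent from the steady-state pool.

## apaQTL mapping

Phenotypes are per-PAS usage ratios of one fraction, one library per
individual. Missing entries are imputed to the row mean (keeping a single
design matrix across PAS), rows centered/scaled and rank inverse-normal
transformed with offset (rank − ½)/n and average ranks for ties; rows that
are constant or observed in fewer than 5 individuals are dropped. Any
monotone transform of a row yields identical output, which is the property
the tests pin; the offset itself is a convention.

Covariates are the top 4 PCs of the phenotype matrix (individuals as
observations) plus one-hot batch with a dropped reference level; the
regression adds the intercept. The cis window is ±25 kb around the PAS,
inclusive at the boundary. Nominal tests residualize phenotype and dosage on
the covariates and use the OLS t-test with n − q − 1 degrees of freedom.

The permutation pass permutes the phenotype vector across individuals
(covariates stay attached to the genotypes), recomputes the window's minimum
nominal p each round via a vectorized correlation identity, and reports
p = (1 + #{perm ≤ obs}) / (B + 1), bounded below by 1/(B+1). The empirical
scheme is primary; no beta-approximation shortcut is used. BH at 10% runs
over all PAS-level permutation p-values within a fraction jointly. Because a
genotype effect on one PAS redistributes usage across all of the gene's PAS
(ratios sum to one), every PAS of a planted gene is a genuine association;
recovery metrics therefore score discoveries at gene level and report a
per-gene rollup alongside PAS-level records.

Raw-scale slopes re-fit the lead variant against the pre-normalized usage
ratio with the same covariates, giving Δusage per alternate allele; a
constant genotype yields a missing slope.

## Sharing and downstream statistics

π0 is estimated on the λ grid 0.05–0.95 (step 0.05) as
#{p > λ}/(n(1−λ)); the default final estimate evaluates a cubic polynomial
smooth of π0(λ) at the largest λ (a "terminal" mean-of-top-three option is
exposed; the invariants hold for either), clips to [0, 1], and π1 = 1 − π0.
The estimator carries the usual conservative bias when non-null p-values
have mass near 1; accuracy claims in the tests use strongly skewed
alternatives (Beta(0.02, 1)), which is what replicated QTL p-values look
like. Fewer than 20 p-values is an error.

Effect concordance is Pearson r plus the OLS slope of one fraction's lead
slopes on the other's. Category enrichment uses one-sided Wilcoxon rank-sum
tests of association p-values against a background group (exact for small
tie-free samples). External QTL overlap takes, per gene, the most
significant nominal p for the queried variant across the gene's K tested
PAS, Bonferroni-corrects by K and flags adjusted p < 0.05. Annotation
overlap resamples the variant set with replacement (default 1000×) for
percentile confidence intervals.

## The synthetic generator

What it emulates: tens of individuals each with one nuclear and one total
library; genes with 2–3 PAS (always a distal 3'UTR site; extras intronic
with probability 0.5, otherwise proximal 3'UTR); baseline logits uniform on
[−0.8, 0.8]; multinomial counts at Poisson(300) reads per gene and library;
read 3'-ends jittered by a truncated discrete Gaussian over ±3 bases
(peak width 7, σ = width/4); planted signal hexamers 15–45 bp upstream of
true PAS with category-dependent probability (0.75 for 3'UTR, 0.25 for
intron — chosen to emulate the observed 3'UTR-vs-intron contrast);
genotypes at MAF uniform on [0.05, 0.5] with the sample-MAF floor enforced
by redrawing; planted cis effects |β| = 1.5 (random sign) on one PAS of 10%
of genes, causal variant within 10 kb of the target site; intronic-isoform
survival 0.3 in the total fraction — strong decay, chosen because weaker
decay (e.g. s = 0.5) cannot move ΔPAU past the 0.2 labelling threshold at
any admissible baseline usage, whereas the phenomenon being modelled is
precisely the strongly nuclear-enriched intronic site; A-rich
internal-priming traps in 10% of genes, half built to trip the read-level
rule (≥ 6 A immediately downstream) and half the site-level rule (an
11-of-15 A pattern that passes the 10-base read window). Flanks of true PAS
are kept A-poor (P(A) = 0.15, runs capped at 2) so that, by construction,
no true site looks internally primed. One chromosome per 50 genes, genes
non-overlapping with gene-free 5 kb downstream regions, all plus-strand by
default with a mixed-strand flag. Optional knobs: Dirichlet-multinomial
overdispersion of the per-sample proportions (off by default), a batch
logit shift on the distal PAS, LD-free genotypes only.

Randomness: one master seed; the truth, genotype and per-library streams are
derived from (seed, stage, individual, fraction) tuples via numpy's seed
sequences, so libraries are independent yet byte-reproducible.

What it does not emulate — and hence what passing tests do not show about
real data: sequencing error and base quality, alignment ambiguity and
allelic mapping bias, linkage disequilibrium, expression-level variation
between genes, overlapping genes and antisense transcription, polyA-tail
dynamics, and any relationship between decay and 3'UTR content beyond the
single survival factor. Recovery rates near 100% on synthetic data reflect
the cleanliness of this design at the chosen depth, not expected real-data
performance; the value of the tests is in calibration (null uniformity,
FDR control) and in exactness of the deterministic components.

## Problem sizes and determinism

The analysis scripts and the acceptance script run the full design at 300
genes × 52 individuals × 2 fractions (~9 M reads), 200 permutations per PAS,
500 null genes for calibration and 10,000 p-values per sharing mixture;
together they complete in a few minutes on one CPU. All stochastic steps
take explicit seeds and are reproducible bit-for-bit; bootstrap and
permutation outputs are deterministic given (data, seed, B).

## Known limitations

- The DM LRT leans on the χ² asymptotics; at very low depth or K near the
  sample count the test can drift from nominal levels (the calibration test
  covers the supported regime, ~200 reads/gene, 20+20 samples).
- With B permutations the permutation p floor is 1/(B+1); at small B and few
  tested PAS, BH at 10% can be unable to call anything — B = 200 with
  several hundred PAS is the practical lower end.
- The π0 smoother is a cubic polynomial fit, not a spline with df selection;
  for adversarial p-value shapes the terminal option is the safer choice.
- `quantify_usage` assumes peak spans from the internal caller are disjoint;
  externally supplied overlapping spans are counted into every matching
  span, which double-counts gene totals by design.
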