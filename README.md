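# apaqtl

Mapping genetic effects on alternative polyadenylation (APA) from 3'-Seq
data. The package implements the full analysis chain for a two-fraction
(nuclear and whole-cell) 3'-Seq study design: polyadenylation-site (PAS)
discovery from read 3'-end coverage, internal-priming artifact removal,
per-gene usage quantification, signal-site scanning, nuclear-vs-total
differential usage testing, cis-apaQTL mapping with permutation-based FDR,
and cross-dataset sharing statistics. A first-class synthetic-data module
generates complete studies with known ground truth, so every stage is
testable end to end without any external download.

## Who this is for

Computational genomicists analysing QuantSeq-style 3'-end libraries across
genotyped individuals, and anyone who wants a transparent, fully tested
reference implementation of the APA-QTL analysis stack (peak calling →
usage ratios → Dirichlet-multinomial differential usage → permutation QTL
scan → Storey π1 sharing).

## The model in brief

**Usage ratios.** For gene *g* with PAS *k* = 1..K, usage in library *s* is
`u_ks = c_ks / Σ_j c_js` — reads at the site over reads at all of the gene's
sites. A PAS is kept when its mean usage reaches 5% in the nuclear or the
total libraries.

**Differential usage.** Counts per gene are modelled as
Dirichlet-multinomial with proportions **p** and concentration α₀. The null
shares **p** across fractions, the alternative fits one **p** per fraction
(α₀ shared); 2·Δlog L is referred to χ²(K−1). Effect size is
ΔPAU = mean total usage − mean nuclear usage; ΔPAU ≤ −0.2 within an
FDR-significant gene marks a nuclear-enriched site — the signature of an
isoform that is degraded or retained before reaching the cytoplasmic pool.

**apaQTL scan.** Per fraction, usage ratios are rank inverse-normal
transformed (offset (rank−½)/n), adjusted for the top 4 phenotype PCs and
library batch, and each PAS is tested against every variant within ±25 kb by
covariate-residualized OLS. Site-level significance uses an empirical
permutation pass (B permutations of the phenotype; p = (1 + #{perm min-p ≤
observed}) / (B+1)) followed by Benjamini–Hochberg at 10% across all PAS of
the fraction. Interpretable slopes are re-estimated on the pre-normalized
ratios (Δusage per alternate allele). Sharing between fractions is
1 − π0 (Storey) over the replication p-values of lead associations.

**Generative model (synthetic studies).** PAS choice is a per-gene softmax
over baseline logits; a planted cis variant adds β·dosage to one PAS's
logit; in the total fraction, intronic-PAS isoforms survive decay with
factor s and proportions renormalize. Read 3'-ends jitter around the true
site; A-rich internal-priming traps emit artifact reads; signal hexamers
(AATAAA and variants) are planted 15–45 bp upstream of true sites with
category-dependent probability.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic design (300 genes, 52 individuals × 2 fractions, ~9.4 M reads) and
write their tables to `results/`:

```
$ python analysis/01_simulate_study.py
genes: 300  true PAS: 721
PAS per category: {'utr3': 513, 'intron': 208}
planted apaQTLs: 30  traps: 25

$ python analysis/02_discover_pas.py
peaks called: 732
PAS after all filters: 719 (12 removed as likely internal priming)
true PAS recovered: 99.7% of 721
artifact traps still present: 0 of 25

$ python analysis/03_signal_sites.py
intron                 signal rate  36.4%  (n=206)
utr3                   signal rate  78.8%  (n=513)
intronic_background    signal rate  10.7%  (n=2000)
3'UTR vs intron difference of proportions: z = 10.89, p = 1.34e-27

$ python analysis/04_fraction_comparison.py
genes tested: 300  significant at 10% FDR: 183
genes with an intronic PAS (planted decay): 179; detected: 178
PAS labelled |dPAU| > 0.2: 222 (113 nuclear-enriched)

$ python analysis/05_map_apaqtls.py
[nuclear] tested PAS: 719  significant: 75  in planted genes: 68  planted genes recovered: 29/30
[total] tested PAS: 719  significant: 76  in planted genes: 69  planted genes recovered: 29/30

$ python analysis/06_sharing_and_concordance.py
sharing pi1 = 1.000   slope concordance r = 0.963 (r^2 = 0.927, slope = 0.992)
```

Reading the output: essentially every planted cleavage site is recovered
while all 25 internal-priming traps are purged; 3'UTR sites carry a signal
hexamer 10–50 bp upstream far more often than intronic sites (both above the
random intronic background); genes with a decaying intronic isoform are
detected with nuclear-enriched ΔPAU; 29 of 30 planted apaQTL genes are
found in each fraction with closely matching effect sizes across fractions.

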