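# Methods

## The screening model

The pipeline searches for lncRNA–miRNA–mRNA triplets consistent with
competing-endogenous-RNA (ceRNA) regulation. The observable signature is a
sign-constrained correlation pattern across samples: writing r_s for
Spearman's rank correlation of expression,

- r_s(miRNA, lncRNA) ≤ −0.33 and q < 0.05,
- r_s(miRNA, mRNA) ≤ −0.33 and q < 0.05,
- r_s(lncRNA, mRNA) ≥ 0.4 and q < 0.05,

with q the Benjamini–Hochberg adjusted p-value computed *within each of the
three pair-type families separately* (the families are screened as separate
hypothesis sets; a global adjustment would couple them for no design
reason). Both cutoffs are inclusive: a pair sitting exactly at −0.33 or
0.4 is retained, reading the published thresholds as attained values. The
lncRNA–mRNA screen keeps positive correlations only by default — the sign
the ceRNA model predicts — with a `two_sided_lnc_mrna` option for the
broader screen.

A triplet is emitted exactly when all three edges survive; this is
literally a triple join and is property-tested against an exhaustive
triple loop. Correlation evidence alone cannot distinguish direct binding
from co-regulation, so the final filter requires sequence support:
canonical miRNA seed sites on *both* the lncRNA and the mRNA.

## Statistics

**Spearman correlation.** rho is the Pearson correlation of mid-ranks
(tie-corrected). Two-sided p-values come from the t approximation
t = rho·sqrt((n−2)/(1−rho²)) with n−2 df; for n ≤ 8 the p-value is exact,
by enumerating all n! pairings of the rank vectors (permuting raw values
permutes mid-ranks, so the enumeration is over permutations of the rank
vector and is valid under ties). A constant vector raises an error rather
than returning a silent 0. At n = 8 the t approximation tracks the exact
p-value to about 0.01–0.03 near the 0.05 level, which is why the exact
path exists for small cohorts.

**Mann–Whitney differential expression.** The group test is the two-sided
Mann–Whitney U: exact enumeration of all C(n1+n2, n1) labelings when both
groups have ≤ 8 samples (exact under ties), otherwise the normal
approximation with tie and continuity corrections. The reported logFC is
median(log2(x+1), tumor) − median(log2(x+1), normal): a robust,
fully-specified location contrast chosen deliberately over a fitted
linear-model effect, and used consistently for both the database-scale and
cohort-scale screens. The substitution is recorded in output provenance
headers. Pseudocount 1 and type-7 (linear-interpolation) quantiles are
fixed conventions throughout.

**FDR.** Benjamini–Hochberg step-up, q(i) = min_{j≥i} m·p(j)/j, clamped at
1. Default significance is q < 0.05; the stricter 0.01 level used for some
published screens is available by setting `alpha`.

**Filters.** Presence: a feature must be > 0 in strictly more than 70 % of
samples ("more than" is read strictly; at 10 samples, 8 positive pass,
7 do not). Variance: IQR of log2(x+1) strictly greater than 0.5. The
variance filter applies to the lncRNA/mRNA classes whose differential
expression drives the screen; the presence filter applies to all classes.

## Seed-site scanner

Canonical sites only, per the standard site-type vocabulary: with the seed
as miRNA nt 2–7 (6mer core) or 2–8, the target-strand motifs are the
reverse complements of the seed (RNA→DNA), the A1 types appending an `A`
opposite miRNA position 1 regardless of that position's identity. Each
occurrence of the 6mer core is reported once, classified as the
highest-priority type matching at that locus (8mer > 7mer-m8 > 7mer-A1 >
6mer) — an 8mer locus is never additionally counted as its nested 7mers.
Coordinates are 1-based closed intervals over the matched motif. No GU
wobble, 3′-supplementary pairing, or context scoring: published triplet
tables report site-type labels only, and the filter needs exactly that.
The scanner works on whatever transcript sequence is supplied; genomic
coordinate lifting is out of scope.

## Synthetic cohorts

The generator emulates a matched tumor/normal expression study with known
ground truth; it is the basis of all recovery tests.

- **Correlation structure.** Each planted triplet gets a full 3×3 latent
  Gaussian correlation matrix (one shared factor cannot hit three
  arbitrary targets). Latent Pearson entries are calibrated from the
  Spearman targets by r = 2·sin(π·r_s/6), the exact bivariate-normal
  relation, so the *rank* correlations of the emitted counts converge to
  the targets. Non-positive-semi-definite targets raise an error naming
  the triplet. Planted feature ids must be distinct across triplets;
  overlapping triplets would need a joint correlation model the generator
  does not attempt.
- **Marginals.** Negative binomial via quantile-mapping the latent normal
  CDF; mean 2^6 = 64 counts (a moderately expressed gene), size
  (dispersion) 5, i.e. variance μ + μ²/5 — overdispersion typical of bulk
  RNA-seq. Transcript lengths: miRNAs 22 nt, lncRNA/mRNA uniform
  500–3000 nt, so FPKM normalization is exercised nontrivially.
- **Fold changes.** A planted log2FC scales the tumor-group negative-
  binomial mean by 2^logFC inside the quantile map, leaving the copula
  untouched; the median-log2 contrast recovers it to within sampling
  error.
- **Dropout** zeroes entries independently with the configured rate
  *after* the correlated draw, mimicking transcripts undetected in part of
  the samples; it degrades, rather than redefines, planted structure.
- **Sequences.** Requested sites are inserted at a recorded position in a
  random background that is rejection-sampled until scanning every
  simulated miRNA against the sequence yields exactly the planted site and
  no other (not even a stray 6mer). Mature miRNA sequences are supplied in
  the config — nothing is fetched.
- **Ct tables.** Target Ct equals the reference level shifted by −logFC in
  tumor rows, with independent Gaussian technical noise (default SD
  0.2 cycles) on every measured value including references. The Gaussian
  noise model is a stand-in; replicate-level qPCR noise structure is not
  modeled.

What the generator does **not** emulate: batch effects, library-size
gradients, count–length coupling, paired-sample correlation between
matched tissues, and read-level artifacts. Passing recovery tests
therefore demonstrates the pipeline's statistical machinery, not
robustness to those real-data complications.

## Recovery experiments (as run in the test suite)

- Copula calibration: one triplet, targets (−0.5, −0.5, 0.6), 5000
  samples; empirical Spearman within ±0.03 (±0.05 at 2000).
- Triplet recovery: 20 seeded cohorts of 300 samples, three planted
  triplets with |r_s| in [0.5, 0.7], 20 decoys per class; sensitivity
  ≥ 0.9, false-discovery proportion ≤ 0.1. These runs disable the
  differential-expression gate (planted fold changes are 0, isolating the
  correlation screen — the component the experiment measures).
- qPCR: planted logFC −2.1, 46 pairs, noise 0.2; median recovered within
  ±0.2.

## GSEA

Preranked only: the running sum rises by |m_i|^p / Σ_set |m_j|^p at set
members and falls by 1/(N−k) elsewhere; ES is the signed extremum, p = 1
by default. The null permutes gene labels (random same-size sets), the
appropriate null when only a ranking exists; p = (1 + #{|ES*| ≥ |ES|}) /
(n_perm + 1), NES = ES / mean|ES*| over same-signed permutations, BH
across sets. Ranking ties break by metric then lexicographic id, so runs
are reproducible when gene-set-style metrics contain ties. Set-size bounds
default to 5–500; an all-zero-weight set falls back to the unweighted KS
statistic rather than dividing by zero.

## qPCR arithmetic

ΔCt = Ct_target − Ct_ref with B2M as reference for mRNA/lncRNA and the
arithmetic mean of RNU48 and RNU6 for miRNA; ΔΔCt = ΔCt_tumor −
ΔCt_normal per matched pair; relative expression 2^(−ΔΔCt) with
amplification efficiency fixed at 2 (no efficiency calibration is
modeled). The per-target logFC is the **median** of −ΔΔCt across pairs
(robust to the outlying pairs such cohorts show; mean vs median is
otherwise unspecified by convention). The default group test is
Mann–Whitney on the ΔCt distributions; for matched pairs the Wilcoxon
signed-rank test is statistically preferable and available as
`paired_test=True`. A target observed in a single pair gets NaN p/q.

## Degenerate inputs and numerical conventions

Constant features are excluded from the correlation screen (undefined
correlation) and raise on direct calls; rho is clipped to [−1, 1] against
floating-point overshoot before the t transform; |rho| = 1 maps to p = 0
in the t path; BH inputs outside [0, 1] raise. Exports sort nodes, edges,
and triplets lexicographically, and the pipeline manifest (version,
thresholds, seed, input SHA-256 hashes) makes reruns byte-identical.

## Known limitations

- Correlations are computed across the pooled tumor+normal sample set;
  planted fold changes with concordant signs therefore add between-group
  correlation on top of the copula (as they would in a real pooled
  cohort).
- The seed filter treats any canonical site as support; it does not score
  site context or count multiple sites.
- The DE module is rank-based and unpaired; paired designs and
  precision-weighted linear models are out of scope.
- Triplet significance is not itself tested (no hypergeometric or
  conditional ceRNA score); the screen's error control lives entirely in
  the per-family FDR and cutoffs.
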