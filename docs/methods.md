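# Methods

## Overview

`panmir` implements a pan-cancer analysis of miRNA-mediated regulation of
cancer-hallmark biology in four linked stages, run per cancer-type cohort
and aggregated across cohorts:

1. **Signature association.** Each sample's hallmark phenotype is proxied by
   a gene-signature score — the median log2(x+1) expression of the signature
   genes. Per cancer type, the standardized score is regressed on the
   standardized log2 expression of every detection-filtered miRNA with an
   L1/L2 penalised linear model, preceded by a permissive univariate F-test
   filter (p < 0.2). Coefficients are aggregated across cancer types with
   the rank product; miRNAs with estimated false-positive proportion
   (pfp) < 0.05 in either orientation are the signature-associated set.
2. **Target screening.** Candidate miRNA→target pairs (a precomputed
   prediction map, minimum two supporting databases) are scored per cancer
   type by the Spearman correlation of miRNA vs target mRNA expression,
   partial to the target's binary non-silent mutation status. Cells are
   recorded only at two-sided p < 0.05 (asymptotic t), else NA. Pairs
   recorded in ≥ 5 types are aggregated with the most-negative-first rank
   product; repressed targets are tested for tumour-suppressor-gene (TSG)
   enrichment with Fisher's exact test and against a bootstrap null that
   redraws random miRNA lists of the same length and reruns the screen.
3. **TSG regulation.** For selected TSGs, standardized log2 expression is
   regressed (same penalised model) on copy-number dosage, one indicator
   per observed mutation classification, the gene's methylation probes, and
   the whole detection-filtered miRNA layer; predictors are aggregated
   across types with the rank product.
4. **Exclusivity.** For a TSG's negative regulators, split into miRNA set A
   and methylation-probe set B, Π_AA / Π_BB / Π_AB are the fractions of
   within- and cross-set variable pairs with significant positive Spearman
   co-correlation (p < 0.05 and ρ > 0). The pairwise differences
   D1 = Π_AA − Π_AB, D2 = Π_BB − Π_AB, D3 = Π_AA − Π_BB are placed on a
   bootstrap null that resamples |A| miRNAs and |B| probes from the cohort;
   high D1/D2 ecdf percentiles indicate mutually exclusive regulation
   (within-set coherence without cross-set co-activation).

## Preprocessing conventions

- Raw expression is transformed by log2(x+1); "at least 80% non-zero"
  detection filtering is inclusive (≥), with zero meaning exactly 0 after
  parsing — no epsilon.
- Standardization is to mean 0 and unit sample (n−1) standard deviation;
  zero-variance covariates are dropped with a logged warning.
- The non-silent mutation vocabulary is the standard MAF set
  (Missense/Nonsense/Frame_Shift/In_Frame/Splice_Site/Nonstop/
  Translation_Start_Site); Silent and Intron records do not set the binary
  mutation flag but do contribute mutation-type indicator columns in the
  TSG design, where classifications are modelled separately.
- A cohort's analysis samples are the intersection of the sample ids of the
  omics layers a stage requires, in mRNA-layer order; cohorts with fewer
  than nine aligned samples are excluded.
- Missing cells in numeric input tables are a parse error: NA semantics are
  introduced explicitly downstream (filtered-out = NA, penalised-to-zero =
  0), never silently at load.

## Penalised regression

The objective is the Gaussian log-likelihood penalised by both norms,

    maximise  −½‖y − Xβ‖² − λ₁Σ|β_j| − λ₂Σβ_j².

λ₂ is searched on the fixed grid (0, 0.01, 0.1, 1, 10, 100). For each λ₂,
λ₁ is profiled over 40 log-spaced values from λ₁_max (the smallest penalty
giving the all-zero model, max_j |x_jᵀy| on centred data) down to
λ₁_max·10⁻³. Model selection maximises the 10-fold cross-validated held-out
Gaussian log-likelihood, computed with the training-fold coefficients and
training-fold maximum-likelihood residual variance; "least predictive
error" and "greatest log-likelihood" coincide under this likelihood. The
fold partition is a seeded random split reused across the whole (λ₁, λ₂)
grid for comparability; the winning pair is refit on the full data
(warm-started down the λ₁ path). The inner solve at fixed penalties is
scikit-learn coordinate descent via the exact reparametrisation
α = (λ₁ + 2λ₂)/n, l1_ratio = λ₁/(λ₁ + 2λ₂); with λ₁ = λ₂ = 0 the solver is
ordinary least squares. Coordinate-descent tolerance is 10⁻⁴ with
per-training-fold precomputed Gram matrices — coefficient differences from
a tighter tolerance are orders of magnitude below the rank resolution that
downstream aggregation consumes. The intercept is unpenalised (handled by
centring) and is ≈ 0 for standardized responses.

Filtered-out miRNAs (detection or univariate filter) are recorded as NA in
the coefficient matrix — "not assessed"; miRNAs penalised exactly to zero
are recorded as 0 and participate in downstream ranking at tied mid-ranks,
as evidence of non-association.

## Rank product

Within each list (cancer type) values are fractionally ranked (ties get the
mean of the spanned ranks) over every non-NA cell; an item's rank product is
the geometric mean of its ranks normalized by the per-list non-NA count
n_k, over the lists where it was assessed. Both orientations are computed:
descending ("up", consistently large) and ascending ("down", consistently
negative). The null holds each item's rank uniform on 1..n_k independently
across lists — the marginal of within-list permutations. Items sharing a
missingness pattern share null draws; p uses the add-one estimator
(b+1)/(B+1) with B = 10,000 by default, and an exact enumeration over the
rank lattice replaces sampling whenever ∏ n_k ≤ 10⁶ (this exact mode also
serves as the test oracle for the sampler). pfp_i = p_i · n/rank(p_i), the
expected-false-positive convention; "significant" means pfp < 0.05.

Two scope decisions matter. Items assessed in fewer than `min_lists` types
are excluded from the output but still occupy ranks, so survivors are
measured against the full field. And when a miRNA *list* is screened (the
signature-associated set, or a bootstrap resample), per-type ranks are
computed over **all** candidate pairs while aggregation and the pfp
correction are restricted to the list's pairs: a pair's consistency is
always judged against the complete candidate field, not only against its
own list — restricting the rank scale to a list whose pairs are largely
true repressions would erase exactly the signal being sought.

## Partial Spearman correlation

Fractional ranks of x, y, z feed the first-order Pearson recursion
ρ_xy·z = (ρ_xy − ρ_xz ρ_yz)/√((1−ρ_xz²)(1−ρ_yz²)); two-sided p from
t = ρ√((n−3)/(1−ρ²)) on n−3 df. A constant covariate (unmutated gene)
falls back to the plain Spearman correlation on n−2 df; |ρ_xz| = 1 or
|ρ_yz| = 1 leaves the partial correlation undefined (NA). The recursion and
residual-on-ranks regression agree to ~10⁻¹⁰ on untied data; the recursion
is the implementation, the residualisation the test oracle.

## Enrichment and bootstrap nulls

Fisher enrichment uses the exact hypergeometric test on the 2×2 table of
{repressed target / not} × {annotated TSG / not}. The universe is every
unique gene appearing as a candidate target that was evaluable after
detection filtering — the set of genes that could have been called. The
repressed-TSG bootstrap draws `list_length` miRNAs uniformly without
replacement from the detection-eligible pool (B = 1000), reruns the full
screen for each list, and reports the observed count's plain ecdf
percentile #{null ≤ obs}/B together with p_upper = 1 − percentile and the
add-one smoothed upper p. The exclusivity bootstrap likewise resamples
regulator sets of the observed shape without replacement within each
feature class; observed regulators stay in the pool (the conservative
null). All bootstrap seeds derive deterministically from the stage seed.

## Synthetic cohort generator

The generator emulates the data-generating structure the pipeline assumes,
with planted ground truth recorded in machine-readable tables:

- Per cohort and signature, a latent hallmark phenotype h ~ N(0,1) per
  sample; signature genes add 1.0·h to a U(5,9) baseline with N(0,1) noise.
- Driver miRNAs add ±0.4·h (the standardized study effect; half positive,
  half negative) to a U(4,8) baseline with N(0,1) noise. Because each
  driver carries independent unit noise, drivers are only mildly
  inter-correlated (~0.15) and the elastic net retains them all rather than
  collapsing the group onto one representative.
- Repressive pairs subtract |slope|·(miRNA − mean) from the target's
  log-expression, with pair-specific noise (study conditions: 40 pairs,
  slope −0.5, noise sd 1, targets inside the 140-gene synthetic TSG list,
  hidden among 2000 candidate pairs; 100 extra single-source decoy rows
  exercise the min-two-sources load filter).
- Copy number is integer dosage in {−2..2} (P(±1) = 0.08, P(±2) = 0.02)
  adding 0.6·CNV; mutations are Bernoulli(0.02) per gene and sample with a
  MAF-like classification mix, and any non-silent event subtracts 1.0.
- Methylation probes carry a per-gene latent level (beta ≈ 0.35 ± 0.08 on
  the gene level, ±0.05 probe noise, clipped to [0.01, 0.99]), so probes of
  one gene co-correlate as they do on real arrays.
- Regulation-mode TSGs have 5 cognate miRNAs and 5 cognate probes. In
  `exclusive` mode a per-sample Bernoulli(½) arm indicator raises the
  cognate miRNAs (+1.5 log-units) XOR the cognate probes (+0.3 beta); in
  `cooccurring` mode one indicator raises both. The gene's expression is
  repressed by both regulator means plus CNV, mutation and N(0, 0.5) noise.
- 10% of genes and miRNAs are generated at near-zero baseline so the
  detection filter is exercised; expression layers are emitted on the raw
  scale (2^x − 1, clipped at 0) so the pipeline's own log transform runs.

All sampling flows from one seeded PCG64 generator in a fixed documented
order (phenotypes → CNV → mutations → methylation → arms → miRNA → mRNA per
cohort, then the target map), so identical configurations are byte-identical.

What the generator does **not** emulate: RNA-seq count noise
(mean-variance coupling, library size), batch effects, tumour purity,
realistic miRNA family structure, and LD-like correlation among decoy
pairs. Passing recovery tests therefore demonstrates that the statistical
machinery detects the planted effect structure at realistic effect sizes
and sample counts — not that the pipeline is robust to every artefact of
real TCGA data.

## Problem sizes and seeds

The standard study conditions are 6 cohorts × 150 samples, 300 miRNAs, 800
genes, 300 probes. Recovery and calibration experiments
(`panmir.experiments`) run 20 seeds for driver recovery, exclusivity
discrimination and null false-positive control; the bootstrap nulls use
B = 1000; rank-product permutation p-values use B = 10,000 (2000 inside the
bootstrap screens, where only a detection threshold — pfp < 0.05 with
p-values no smaller than ~5·10⁻⁴ — is needed). The end-to-end determinism
check uses a reduced configuration (6 × 60 samples, 80 miRNAs, 300 genes)
so two full pipeline runs complete quickly; every stage receives a child
seed derived by hashing the master seed with the stage name.

## Known limitations

- Rank-product p-values on heavily tied inputs (e.g. many exactly-zero
  penalised coefficients under the global null) are conservative, not
  uniform: the observed mid-ranks sit near the centre of the uniform null.
  False-positive control holds; literal p uniformity is a property of
  continuous inputs only.
- The permutation null treats within-list ranks as independent across
  items (exact for the marginal per-item p; pfp across strongly dependent
  items is the usual RankProd approximation).
- The univariate F-filter and the subsequent penalised fit reuse the same
  data; pfp calibration absorbs the selection, as in the original design.
- With p ≫ n designs (the TSG models: one column per miRNA), the λ₁ path
  lower bound (10⁻³·λ₁_max) keeps the solution well-regularised; truly
  unpenalised fits in that regime are not identifiable and are not
  attempted by the CV search.
- Exclusivity percentiles are plain ecdf values of a discrete statistic;
  with small regulator sets the null has atoms and percentiles are
  correspondingly coarse.
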