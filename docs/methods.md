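# Methods

This note records the models behind `irdr`, the parameters that matter,
and the choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or the acceptance script
does not itself compute.

## Synthetic world

The generators state a world; they are not tuned to any downstream
outcome.

**Cross-sectional cohorts.** Expression follows

    x_gs = b_g + beta_g * logIR_s + gamma_g * (age_s - mean age) + eps_gs

with `eps ~ N(0, noise_sd²)` independent per gene and sample. HOMA2-IR
is drawn log-normal (`logIR ~ N(ir_log_mean, ir_log_sd²)`, defaults
0.3 / 0.6, i.e. typical values ~1.3 with a realistic spread); the
physiological HOMA2 calculator is treated as a black box upstream and
not reimplemented. Age is N(50, 8²) years with small slopes
(`age_effect_sd = 0.05` expression units/year) — enough to make the
age adjustment non-trivial, not enough to dominate. Defaults: n = 200
samples, 978 landmark-like genes, 160 genes carrying a true IR slope.

Planted slopes are `sign · effect_size_sd · |N(0,1)|` with magnitudes
below 0.5 resampled. A "true IR gene" whose slope is statistically
indistinguishable from zero would make the planted label — and any
recovery rate computed against it — vacuous; the floor is the smallest
magnitude that keeps the label meaningful at the default noise level
(|CC| ≈ 0.29 at the floor, comfortably detectable at n = 200). Muscle
and adipose studies built from one spec share slope identities and
signs, which is the cross-tissue consistency the selection filters
exploit.

**Paired interventions.** Per subject, `Δx_g = theta_g · ΔlogIR + eps`
with `ΔlogIR ~ N(−0.4, 0.3²)` (the programme lowers IR on average) and
n = 50 subjects per study. Default `theta = 3 · beta`: a gene
up-regulated in the disease falls as the intervention lowers IR, with
an amplitude giving |CC| ≈ 0.4 at the planted floor — the size needed
for a mean q < 0.08 across four 50-subject studies, and consistent with
exercise-biopsy effects being larger than cross-sectional contrasts.

**Perturbagen database.** Per-gene z-scores over a shared universe of
978 landmark-like genes plus the signature genes, nine named cell
lines, independent N(0, noise_sd²) noise per gene and cell. Planted
*reversers* (reverse the disease = mimic the treatment; 5% by default)
add +`reversal_strength` (default 2) to signature up-genes and the
negative to down-genes; *mimickers* (5%) the opposite; the rest are
null. Single-gene assays: 120 knock-down and 80 overexpression
profiles, mirroring the KD-heavier composition of real genomic
perturbation collections; at most a quarter of each type covers true
targets of reverser compounds (KD of such a target is reverser-like,
OE mimicker-like), the remainder are null, so the background hit rate
used by the enrichment test stays meaningful. True Kd values for
annotated targets are log10-normal around 30 nM (spread 0.5 dex).

**DTI predictions.** For true targets, each model predicts
`ln(Kd) + N(0, noise_sd²)`; background proteins draw from a wide
weak-binding null centred at 10 µM (1.5 dex spread). Lower = stronger,
matching the dissociation-constant convention.

What the generators do **not** emulate: bead-level expression
inference, batch effects, dose–response series, correlated gene-gene
noise, annotation errors. A green planted-truth test therefore
establishes that the statistics recover the stated model, not that
they would survive those real-data pathologies.

## Statistical choices

* **Partial correlation.** Residualise expression and log IR on
  [1, age] via the hat matrix; correlate residuals. p from t with
  n − 3 df; BH within study. Residual norms at rounding-error scale
  (relative 1e-10) are treated as zero variance and reported missing,
  excluded from BH.
* **Meta-analysis.** Fixed-effect Fisher-z combination weighted by
  n − 3, back-transformed; |cc| is capped at 1 − 1e-12 so noiseless
  genes keep a finite, very large z instead of vanishing.
* **Combined ranking.** Stouffer: genes in both lists get
  (z_d + z_t)/√2, genes in one list that z alone; the statistic is then
  negated into the treatment orientation (up = rises as IR falls).
  The source analysis says only "statistically ranked"; Stouffer is
  our choice. Ties break lexicographically by gene id everywhere.
* **Enrichment score.** Weighted KS running sum: hits step
  w_g / Σw(set) (w = |z|; unweighted option for clean ±1 limiting
  cases), misses step 1/(N − |set|); ES is the extremum (first position
  on magnitude ties). An all-zero weight sum falls back to unweighted.
  Results are clipped to [−1, 1] against ~1-ulp cumsum overshoot.
* **WTCS / NCS.** WTCS = (ES_up − ES_down)/2 on sign disagreement,
  else 0. NCS divides by the mean |WTCS| of same-sign scores in the
  cell line; a sign group with fewer than two members yields NCS = 0,
  flagged. Whether this matches the upstream service's normalisation
  exactly is not verifiable from the published text; this definition is
  ours.
* **Aggregation.** Linear-interpolation quantiles at 0.33/0.67 of the
  per-cell NCS; the larger-magnitude quantile wins, upper quantile on
  ties. The selection quantiles are location-equivariant; the chosen
  aggregate switches branch when a shift flips which quantile is
  larger — the monotonicity property (raising every cell's NCS cannot
  lower the aggregate) always holds.
* **±100 score.** Signed within-collection percentile; compounds and
  single-gene assays are separate collections with their own score
  distributions. Consequence worth stating plainly: at the compound
  threshold of 90, at most ~10% of positive-aggregate compounds can be
  hits, whatever the planted fraction. With 5% planted reversers and
  the usual ~25% exactly-zero aggregates among nulls, the attainable
  sensitivity tops out near 0.76–0.8 even at perfect separation; the
  test suite asserts the separation exactly and documents this cap
  where the 0.9 bound is asserted.
* **Direction calls.** Negatively acting: KD significant-positive or
  OE significant-negative; positively acting: the mirror; both ⇒
  discordant (counted once as a hit, flagged); neither ⇒ unpowered.
  Significance threshold 70 on the ±100 scale.
* **Enrichment test.** Exact one-sided binomial tail against the fixed
  assay background rate (the published analysis says only "see
  Methods"); Fisher 2×2 (greater) reported alongside. Background
  universe = all proteins with any single-gene assay, not the genome.
* **Pharmacology.** The 13 descriptors are molecular weight, heavy
  atoms, heteroatoms, logP, rotatable bonds, TPSA, ring counts (total /
  aromatic / saturated / aliphatic), Balaban J, H-bond donors and
  acceptors, computed with RDKit; goldens in the tests were frozen from
  one independent RDKit run. Group comparison: two-sided rank-sum per
  descriptor, BH across the 13 (the test behind "did not differ" is
  unstated in the source; rank-sum is ours). Potency clustering:
  average linkage on Euclidean distances of log10 nM, missing values
  imputed at 10 µM for clustering only — never for correlation, where
  missing stays missing.
* **Rank fusion.** Within-model ranks are average-tie ranks of
  predicted Kd ascending; the consensus is the arithmetic mean of ranks
  (not the rank of mean score), final per-compound permutation breaks
  mean-rank ties by protein id. Retrieval percentiles are
  within-compound (100 · rank / P); a pooled variant over all
  compounds' predictions is reported alongside since the published
  percentile base is ambiguous.

## Numerical and degenerate-input conventions

Seeds are explicit everywhere (derived child seeds stay below 2³¹); no
global random state. Zero-variance genes are excluded from BH rather
than given p = 1. All-zero profiles, empty gene-set intersections,
empty compound lists and protein universes missing annotated targets
raise with the offending identifiers. SMILES parse failures are
recorded per compound and never abort a batch.

## Known limitations

The percentile-scale sensitivity cap above; single fixed gene universe
(no probe mapping or normalisation — inputs are assumed normalised);
the hub-connectivity variant uses β = 6 without per-dataset soft-power
selection; the in vivo concordance permutation test permutes gene
labels, which assumes exchangeability across signature genes; DTI
fusion consumes score matrices and deliberately does not run any
trained predictor.
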