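# Methods

## The generative model

The synthetic screen emulates the statistical structure of a plate-based
ex vivo viability screen on primary CLL samples. Each sample occupies two
384-well culture plates (16 × 24); plate 0 carries the lower drug
concentration, plate 1 the higher. Every plate holds the 12 drug-only wells,
the 17 stimulus-only wells, all 204 drug–stimulus combinations, at least 16
interior DMSO control wells and at least 4 DMSO controls on the outer ring
(rows 1/16, columns 1/24) so that downstream edge exclusion is exercised.

A well's luminescence is

```
lum = base · exp( plate + βd·Xd + βs·Xs + βint·Xd·Xs + ε ),   ε ~ N(0, σ²)
```

with σ = 0.1 on the log scale by default and a per-plate intercept
`plate ~ N(0, 0.1²)` shared by all wells of the plate. Noise is log-normal
because the analysis model is linear in log viability; the shared plate
intercept cancels identically under within-plate normalization, giving a
built-in check that normalization removes plate effects. The per-plate and
well-noise magnitudes are not published quantities; the defaults are
plausible values for luminescence assays and are configurable.

Planted structure, fixed once as the package's default study conditions:

- **Single-agent effects**: drugs are toxic (βd from −0.10 for the mildest
  kinase inhibitors to −0.75 for the HSP90 inhibitor), most stimuli are
  pro-survival (IL4 +0.45, TLR7/8 and TLR9 agonists +0.40/+0.35, sCD40L+IL4
  +0.50), IL6 and TGFβ1 mildly toxic — the qualitative pattern reported for
  such screens.
- **45 interactions** across all four categories (22 I / 6 II / 1 III /
  16 IV): positive antagonistic (IL4 and IFNγ rescuing BCR inhibitors and
  chemotherapeutics), negative antagonistic (JAK/NFκB inhibition blocking
  pro-survival stimulation, BTK inhibition blocking anti-IgM), positive
  synergistic (p38 inhibitor × IFNγ), negative synergistic (TLR agonists
  sensitising to BCR inhibition; HSP90-inhibitor synergies). Magnitudes
  0.10–0.70 were chosen so that each pair's expected pooled coefficients sit
  on the intended side of its category boundary by at least ~0.05.
- **Four latent response clusters** with proportions 0.30/0.15/0.25/0.30:
  C1 and C2 (IGHV-U-enriched) respond strongly to IL4/TLR stimulation, C2
  more strongly and additionally to NFκB agonists; C3 responds weakly to
  most stimuli; C4 loses viability under TLR stimulation. Implemented as
  additive per-cluster stimulus shifts (±0.35–0.45), applied wherever the
  stimulus is present, so interaction factors are unaffected.
- **Genetics**: recurrent aberrations at realistic CLL prevalences, with
  trisomy 12/SF3B1 enriched in C2, POT1 in C3, and TP53/ATM/gain(8q)
  depleted in C4; IGHV-M probability 0.20/0.30/0.80/0.85 per cluster;
  methylation class drawn conditionally on IGHV. Missingness is
  missing-completely-at-random at 5% per feature.
- **Direct genetic response modulation**: trisomy-12 carriers gain
  +0.15…+0.20 on IL4/TLR/sCD40L+IL4 responses and −0.10 on TGFβ1; 12
  drug–stimulus pairs carry genetic interaction modulators (trisomy 12,
  IGHV status, del(11q); ±0.20–0.45).
- **Outcomes**: exponential event times with cluster hazard multipliers
  2.0/2.5/2.2/1.0 (C4 indolent) on a baseline hazard of 1/900 days, censored
  by an independent Uniform(0, 2/censoring-rate) time; censoring rate 0
  disables censoring.

What the generator deliberately does **not** emulate: spatial gradients or
edge effects beyond the control-well layout, dose–response curvature (one
effect per drug regardless of concentration), measurement-batch drift,
feature-block-structured missingness, informative censoring, and any
transcriptomic/epigenomic layer beyond a per-peak ATAC count toy. Passing
tests therefore certify the statistical machinery under the stated model,
not robustness to those real-data artefacts.

## Normalization and scaling

Log relative viability is `ln(lum / median of interior DMSO wells of the
same plate)`; replicate wells of a condition (e.g. stimulus-only wells
present on both plates) are averaged after the log transform. The natural
log is used throughout. Robust z-scores are computed per sample row as
`(x − row median) / max(row MAD, 1e−8)` without the 1.4826 consistency
constant; a copy clipped to ±4 is kept for display. Median-centering is
included because the display scale is signed; the cap and the MAD floor
bound the scaling factor and are both configurable. Pearson correlations
between single treatments
are BH-adjusted separately within the drug block and the stimulus block.

## Consensus clustering

10,000 repetitions by default (tests and examples use 100–1,000): each
repetition draws ⌈0.8·n⌉ samples without replacement, clusters them
hierarchically (Euclidean distance, average linkage) and cuts at each
candidate k; the consensus entry of a sample pair is co-clusterings over
co-samplings. Final labels cut an average-linkage tree of 1 − consensus. k
is chosen by the largest relative change in the area under the consensus
CDF (for the smallest k the area itself, the usual convention), and the
full curve is reported so a user can override it — a four-cluster
stratification is obtained by fixing k = 4.

Two deliberate choices:

- **Input matrix.** Clustering runs on the *unscaled* log-relative-viability
  stimulus profiles, not on the robust-z rows. Row-MAD scaling erases
  amplitude signatures (strong responders are shrunk onto weak ones) and
  turns flat rows with tiny MADs into outliers that average linkage peels
  off as singletons; on generator output it destroys cluster recovery (ARI
  0.41 at k = 4) while the identical procedure on unscaled profiles
  recovers the planted partition exactly. The robust-z matrix remains the
  display scale.
- **Weak-structure flag.** Flatness of the selection curve does not
  distinguish structure from noise for subsampled consensus (on pure noise
  the relative area changes are in fact steeper than on separated
  clusters). The flag instead uses the proportion of ambiguous clustering
  (PAC): the fraction of off-diagonal consensus entries in (0.1, 0.9) at
  the chosen k, with threshold 0.2. Measured PAC is ≈ 0.6 on noise and
  0.00 on separated clouds, so the threshold sits in a wide gulf.

## The interaction model

The pooled fit is ordinary least squares of the no-intercept model on the
drug-only, stimulus-only and combination observations of a pair. DMSO rows
are excluded: under this parameterisation a (0,0) row carries no design
information, and the normalization itself pins those rows near zero, so
including them would deflate the residual variance. With all three
conditions present the fitted values equal the condition means (the three
distinct design rows are linearly independent), giving
`βint = mean(combo) − mean(drug) − mean(stim)`; with unbalanced data the
least-squares solution is authoritative. The p-value is the two-sided t-test
on βint with residual degrees of freedom; `P < 0.05` unadjusted defines
"interaction present" (no multiplicity correction), and category boundary
ties classify as antagonistic (the interaction then exactly cancels the
single-agent effect, which is the antagonism limit). The per-sample fit is
the saturated identity `βint = logV_combo − logV_drug − logV_stim`; its
cohort average equals the pooled balanced estimate.

Two concentrations per drug are kept as separate conditions; the
interaction analysis consumes one effective condition per drug, selected by
policy (`low` by default, `high` and `average` available), matching the
12 × 17 = 204 combination count.

## Stability selection

All three variants resample samples with replacement, standardize
predictors within the resample, fit an L1-penalised model, and count how
often each predictor is selected; reported coefficients are means over the
bootstraps in which the predictor was selected, on the standardized scale.
Default thresholds: gaussian per-stimulus models keep
predictors selected in strictly more than 75% of 30 bootstraps; multinomial
cluster models keep predictors with frequency ≥ 60% *and* |mean
coefficient| ≥ 0.35 over 50 bootstraps; interaction-modulator models demand
strictly more than 90%.

The penalty is chosen by 10-fold cross-validation with the
**one-standard-error rule** (the sparsest model within one SE of the
minimum CV error). Choosing the exact CV minimiser inside a bootstrap
under-penalises systematically — duplicated samples leak between CV folds —
and measured noise-predictor keep rates of ~8% against ≤ 5% expected; the
1-SE rule brings false keeps to ~0 while leaving planted-effect recovery at
100% in the same simulations. For the multinomial model the penalty is
selected once on the full data (by mean CV log-loss, strongest penalty
within one SE) and held fixed across bootstraps; re-running the multinomial
CV path inside every bootstrap would dominate the runtime of the whole
pipeline without changing the selection behaviour. A bootstrap missing a
cluster is redrawn (at most 100 attempts).

Feature encoding: IGHV M = 1 / U = 0; methylation class LP = 0, IP = 0.5,
HP = 1; KRAS/BRAF/NRAS collapsed into one RAS/RAF indicator; features with
more than 20% missing values dropped; complete-case samples only, with
each analysis recomputing its own complete-case set. Univariate tests are
equal-variance two-sided t-tests of carriers vs non-carriers, restricted to
features with ≥ 3 carriers, BH-adjusted across all performed tests at
FDR 10%.

## Survival analysis

Cox models maximise the Efron partial likelihood (lifelines backend, full
Newton steps with tightened tolerances — the damped default stops short of
the optimum on small data). Categorical covariates expand against a
configurable reference level; the cluster reference defaults to the
lexicographically first label, and the indolent cluster serves as the
reference for aggressive-vs-indolent comparisons. Kaplan–Meier estimation
is the product-limit estimator.

Maximally selected rank statistics scan every observed marker value inside
the (0.1, 0.9) marker-quantile window, computing at each cutpoint the
standardized two-group log-rank statistic (hypergeometric variance; equal to
the Cox score test at β = 0 on tie-free data). Significance is assessed by
permuting the marker (default 1,000 permutations, add-one p-value); the
analytic small-sample approximations for the maximally selected statistic
come in many variants and the permutation null avoids committing to one.

## Trisomy-12 ATAC caller

`ratio = mean(counts on chr12) / mean(counts elsewhere)`; a sample is called
trisomic when the ratio strictly exceeds 1.4.

## Problem sizes and numerics

The test suite runs the full machinery at reduced scale: consensus
clustering with 20–200 repetitions, stability selection over 20 seeded
simulations at the stated effect sizes (n = 100–200, 30–50 bootstraps),
interaction recovery on 20 screens of 200 samples, one 100-sample null
screen for calibration. The acceptance script runs the study-scale pipeline
(192 samples, 10,000 consensus repetitions, all 204 pairs through modulator
selection) in roughly ten minutes on one CPU. Numerical tolerances: OLS
agreement with the normal equations to 1e−10; t-test and BH agreement with
textbook formulas to 1e−12/1e−10; Cox agreement with a golden-section
partial-likelihood maximiser to 1e−6; maxstat agrees exactly with an
exhaustive scan. Lasso coordinate descent uses a 60-point penalty path;
saga multinomial fits use tol 1e−3 and a fixed internal random state for
determinism.

## Known limitations

Pooled interaction p-values treat observations as independent although
conditions of a sample share a plate normalizer; the shared term cancels in
βint but inflates the residual variance estimate slightly, making the test
mildly conservative (measured null rejection ≈ 0.04 at α = 0.05). Average
linkage remains fragile to outlying profiles; strongly contaminated data may
warrant Ward linkage, which is not the default here. The modulator scan's
strict 90% threshold trades sensitivity for precision: with ~100
complete-case samples, modulators below ≈ 0.25 log units are frequently
missed. The trisomy caller assumes uniform coverage; GC or copy-number
artefacts outside chromosome 12 would bias the ratio.
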