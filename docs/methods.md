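# Methods

`mirdiscover` implements a two-phase circulating-miRNA biomarker discovery
analysis for endometriosis in adolescents and young adults, together with a
synthetic cohort generator that reproduces the statistical structure the
design relies on — in particular, effect modification by exogenous hormone
use at blood draw. This note documents the models, the parameters that
matter, what the generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Study design being modeled

Two case/control phases, frequency matched on age (within two years, i.e.
4-year age bins anchored at the youngest case) and hormone use (any/none):

- **Discovery**: 10 cases / 10 controls (50% hormone users), ~754 plasma
  miRNAs measured by qPCR in technical duplicate. Output: a candidate list.
- **Internal replication**: 54 cases / 108 controls (78% hormone users),
  a 63-probe bead-panel (fluorescence readout), randomized 2:1 into
  training (36 cases / 72 controls) and testing (18 cases / 36 controls)
  sets. Output: a classifier whose logistic output is the estimated
  probability of disease.

## Discovery-phase statistics (`discovery.py`)

1. **Duplicate collapsing** — a technical pair is replaced by its mean when
   the two replicates agree within `max_duplicate_discordance` (default 1
   cycle); discordant pairs become missing, singletons pass through.
2. **QC** — measurements with Ct > 34 cycles (strictly greater) are
   censored; miRNAs missing in more than 50% of samples are dropped. The
   two levels (per-measurement censoring, per-miRNA drop) are distinct
   rules with separate thresholds.
3. **Outlier exclusion** — iterative Grubbs flagging per miRNA within
   case/control group at α = 0.05 (configurable off). The upstream
   software's exact rule is unpublished; Grubbs is a conservative,
   reproducible stand-in.
4. **Imputation** — a missing value becomes the mean of its miRNA within
   the same (group × hormone stratum) cell, falling back to the miRNA
   grand mean when the cell is empty. Observed values are never altered.
5. **Global normalization** — ΔCt = Ct − per-sample mean over the common
   detected miRNA set. This removes per-sample loading/efficiency shifts
   exactly (the operation is invariant to adding a constant to a sample
   column).
6. **Normfinder reference selection** — for gene *i*, group *g* with group
   mean a_ig, within-group variance v_ig and group size n_g, the
   stability value is

       ρ_i = (1/G) Σ_g ( |d_ig| + √(v_ig / n_g) ),
       d_ig = a_ig − ā_i· − ā_·g + ā_··

   (the unshrunk estimator; an empirical-Bayes shrinkage of d_ig is
   available by config but ranking-irrelevant in our regimes). Lower ρ is
   more stable; the k = 5 smallest-ρ miRNAs become the reference set, ties
   broken lexicographically.
7. **Relative quantification** — ΔΔCt is the case-minus-control difference
   of reference-adjusted ΔCt means; the ratio is 2^−ΔΔCt, displayed in the
   signed convention (ratios < 1 become the negative reciprocal, so
   |FC| ≥ 1 always, matching how candidate tables in this field print
   down-regulation).
8. **Stratified selection** — two-sided pooled-variance (Student's)
   t-tests on reference-adjusted ΔCt, run separately among hormone users
   and non-users (Welch available by config). A miRNA is carried into the
   replication panel iff p < 0.005 in either stratum, or p ≤ 0.05 in both.
   The strict clause takes precedence in the recorded reason. Whether the
   original tests were run on ΔCt or on reference-adjusted ΔCt is not
   documented upstream; we use the reference-adjusted scale for
   consistency with the 2^−ΔΔCt quantification (the two differ only
   through the per-sample reference mean, which is small by construction).

The replication panel is the selected candidates plus 8 literature probes
and 3 + 3 positive/negative assay controls (49 + 8 + 6 = 63 at study scale).

## Replication-phase screen (`replication.py`)

- **Preprocessing** — values ≤ 0 (possible after background correction in
  the assay software) are shifted to 0.001, then log10-transformed. Blank
  wells are summarized only; blank subtraction is config-gated and off by
  default since only the shift + log10 steps are documented. Pooled-QC
  wells are reported as a per-probe CV and excluded from analysis.
- **Univariate screen** — pooled t-tests per probe on training-set log10
  MFI; familywise correction by Holm–Šidák step-down:
  adjusted p_(i) = 1 − (1 − p_(i))^(m − i + 1) over ascending p, monotonized
  by running maximum. Fold change is reported as signed 10^Δ.
- **PCA / clustering separation** — PCA on standardized probe columns;
  separation is the AUC of PC1 scores against labels, folded to ≥ 0.5
  because a principal component's sign is arbitrary; a 2-means clustering
  agreement rate (also folded) covers the unsupervised check.
- **CFS** — merit of a subset S with k features:

      merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff)

  with r̄_cf the mean |point-biserial correlation| with the class and
  r̄_ff the mean pairwise |correlation| within S (Hall's
  symmetric-uncertainty variant is not used; the features are continuous
  and the class binary). Candidates are gated to training-set raw
  p ≤ 0.15. Within each of 10 stratified CV folds the best-first forward
  search (stall limit 5; exhaustive enumeration when the gated pool has
  ≤ 15 probes) maximizes merit with the hormone-use covariate forced into
  every evaluated subset. Per-fold subset aggregation is a majority vote
  (chosen in ≥ 50% of folds) — the original aggregation rule is
  unpublished; majority is deterministic and stable. Hall's
  locally-predictive refinement is implemented but off by default: it
  re-admits weakly class-correlated features and inflates false picks.

## Model construction (`mlp.py`)

Single-hidden-layer perceptrons: hidden size uniform on
[⌈n/3⌉, ⌊1.5n⌋] for n inputs, hidden activation uniform over
{linear, logistic, tanh, exponential} (exponential is f(u) = e^u with the
argument clamped at ±30 for safety), logistic output. Training minimizes
mean binomial cross-entropy plus an L2 penalty (default 10⁻⁴, biases
unpenalized) by BFGS (SciPy's quasi-Newton implementation, analytic
gradients, default 150 iterations) from seeded uniform initialization
(±0.5/√fan-in); a non-finite loss triggers one restart at 5× smaller scale
before the network is recorded as failed. Inputs are standardized to
zero-mean/unit-SD using training-split statistics only; binary 0/1
covariates pass through unstandardized.

The sweep trains `n_networks` independently seeded architectures on the
training split (15,000 at published scale; reduced sweeps are used
throughout testing — see problem sizes below), ranks them by training AUC,
keeps the top 50, and selects the final model by testing-set AUC (ties →
higher training AUC → lower network index). Selecting on the test set is
the published procedure and is optimistically biased; the null-calibration
experiment quantifies that bias rather than hiding it. Models serialize to
JSON losslessly (float64 survives repr round-trip).

## Evaluation (`evaluation.py`)

- **AUC** — computed both as the tie-corrected rank statistic and as the
  trapezoidal area under the threshold-sweep ROC; the implementation
  raises if the two disagree beyond 10⁻⁹.
- **Hanley–McNeil** — SE² = [A(1−A) + (n₁−1)(Q₁−A²) + (n₀−1)(Q₂−A²)]/(n₁n₀)
  with Q₁ = A/(2−A), Q₂ = 2A²/(1+A); two-sided z-test against AUC = 0.5;
  normal-approximation 95% CI clipped to [0,1]. At A = 0.77 with 18 cases
  and 36 controls this gives SE ≈ 0.073 and p ≈ 2×10⁻⁴. Note the study's
  printed CI (0.67–0.87) is narrower than ±1.96·SE at those sizes; the
  software that produced it is unknown, so the printed CI is documented
  but not reproduced.
- **Confusion metrics** — positive iff probability ≥ 0.5 (threshold
  configurable; ties count positive); sensitivity/specificity with exact
  Clopper–Pearson 95% intervals (Wilson by config). The printed-table CIs
  cannot discriminate the CI method after rounding.
- **Sensitivity analysis** — the modeling chain (univariate → CFS →
  ensemble → final selection) reruns with non-pathology-confirmed cases
  removed from both splits; controls and the split assignment are reused
  unchanged.

## Synthetic cohort generator (`simulate.py`)

What it emulates: per-miRNA baselines (Ct ~ U(18,33); log10 MFI ~ U(2,4));
a per-sample global Ct shift (SD 0.5 cycles) that global normalization must
remove; technical duplicate noise (SD 0.2 cycles each); biological +
assay noise (SD 0.2 cycles; 0.15 log10 units ≈ 40% CV on the replication
panel); 2% missingness; reference miRNAs with no biological variance;
blank wells at background fluorescence and pooled-QC replicate wells (5% of
samples); and negative "background-corrected" values created by flipping
the globally dimmest 0.2% of MFI values negative — negativity tracks low
signal, as it does physically. Planted case effects are additive on the
log scale (cycles / log10 units), restricted to the hormone-user stratum,
the non-user stratum, or both, so 2^−ΔΔCt recovers the planted fold change
exactly in expectation. Controls are matched by construction (each case's
controls copy its hormone status and age ± 1 year).

Default planted truth: five probes at |log2FC| = 1 in the stratum pattern
of the discovery candidate table (two hormone-only, two non-user-only, one
both; signs mixed), plus five zero-variance reference miRNAs.

What it does not emulate: correlated miRNA co-expression modules,
heavy-tailed or batch-structured noise, hemolysis or anticoagulant
artifacts, assay saturation, or realistic effect-size spectra — the
original study reports no variance components, so noise levels were chosen
to make planted effects recoverable by a correct implementation (their
stated purpose) while keeping distinct planted probes only weakly
correlated, as distinct real miRNAs would be. Consequently a planted-truth
run looks *cleaner* than the real data: with the default effects, the
univariate screen and PCA do show separation in the emulation, whereas the
study's real replication data showed none after correction. Passing tests
demonstrate the pipeline recovers what was planted under these conditions;
they say nothing about power on real plasma data.

## Standing experiments and problem sizes (`experiments.py`)

- **Null familywise calibration**: 200 effect-free replication cohorts
  (63 probes, n = 162, 78% hormone use); the fraction of replicates with
  zero Holm–Šidák rejections at 0.05 calibrates to ~0.95 by construction.
- **Null ensemble calibration**: 8 replicates × 200 networks on five null
  probes + hormone covariate. The mean testing AUC of the top-50 (chosen
  on training data, hence independent of the test split) calibrates to
  0.5; the final model's testing AUC (test-set-selected) is reported as
  the selection-bias magnitude (~0.55–0.65 in practice).
- **Parameter recovery**: end-to-end pipeline on planted-truth cohorts at
  study shape with balanced hormone strata (the stratum-specific candidate
  pattern originates in the discovery set, which was 50/50; at 78% hormone
  use the non-user stratum's marginal signal is diluted ~4.5-fold and CFS
  legitimately drops it — the default-configuration analysis scripts show
  exactly this). Reduced ensembles (100–200 networks, top 20–50) are used;
  ensemble size affects the final model's variance, not the recovery of
  planted features.

## Known limitations

- CFS recovery of stratum-specific effects at |log2FC| = 1 sits near the
  boundary of the "≥ 4/5 planted probes" requirement: the merit function
  maximizes mean feature quality, so a planted probe whose realized class
  correlation dips toward the null background (sampling SD ≈ 0.1 at
  n = 108) is excluded by design, not by defect.
- Selecting the final network on the testing set (as published) means the
  reported testing AUC is not an unbiased estimate of generalization;
  the null experiments quantify the bias.
- Grubbs outlier flagging and within-cell mean imputation are documented
  stand-ins for unpublished upstream preprocessing.
- The Hanley–McNeil normal interval can exceed [0,1] near boundary AUCs
  (clipped); at AUC = 1 the SE degenerates to 0 and the test is flagged as
  a boundary case instead of reporting a p-value.
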