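# Methods

## The decomposition

A functional-connectivity matrix `C` (Pearson correlations of regional
BOLD series, negatives clipped to zero, diagonal one) is decomposed into
eigenmodes sorted by descending eigenvalue. The nested partition assigns
all regions to one module at level 1; at level `i`, each module splits
into its positive-sign and negative-sign members under eigenvector `i`
(restricted to the module). Modules whose members share one sign are
indivisible and carry forward. The level component is
`H_i = Λ_i² M_i (1 − p_i)/N` with the size-heterogeneity correction
`p_i = Σ_j |m_j − N/M_i| / N`; globally `H_In = H_1/N` and
`H_Se = Σ_{i=2}^N H_i/N`, and regional loadings are
`H_In^j = H_1 U_1j²`, `H_Se^j = Σ_{i≥2} H_i U_ij²` (they sum to
`N·H_In` and `N·H_Se` by eigenvector normalization).

Numerical conventions, each needed because the raw eigenproblem leaves
the quantity undefined:

- **Eigenvector sign**: each column is flipped so its entry-sum is
  positive; if the sum is numerically zero (|Σ| ≤ 1e−12), the
  largest-magnitude entry (first on ties) is made positive. Any global
  flip of a raw eigenvector therefore leaves the partition and all `H`
  values unchanged.
- **Zero entries** join the positive group when splitting. Deterministic
  after canonicalization; empirically irrelevant for generic matrices.
- **Degenerate eigenvalues** (gap < 1e−10) make the partition
  non-unique; a warning is emitted. Sample FC matrices are generically
  non-degenerate.
- **All N levels** are computed; once every module is a singleton the
  remaining levels repeat the singleton partition (where `p_i = 0`), and
  the segregation sum runs over levels 2…N as defined.
- **Negative eigenvalues** (possible after clipping negative
  correlations) are kept and squared as written; sorting is by algebraic
  value.
- Asymmetry beyond 1e−8 is rejected rather than silently symmetrized.

## Dynamics and finite-length calibration

Sliding windows (default 30 frames wide, step 1 — a 60 s window at
TR = 2 s; a 152-frame record gives 123 windows; the count is always
derived from the configured length/width/step) yield per-window
components. Strength is the time-mean and variability (`F_In`, `F_Se`)
the sample (n−1) standard deviation of the windowed trace.

Short records inflate apparent segregation, so static components are
calibrated per group against the group-stable FC computed on the
concatenated record (each subject z-scored per region first, so
between-subject offset/scale differences cannot inflate pooled
correlations): `H′(n) = H(n) · H^S/⟨H⟩`. Regional loadings are rescaled
by the same subject factor (`H^{j′} = H^j · H′(n)/H(n)`, preserving
regional proportions) and each dynamic trace is rescaled so its
time-mean equals the subject's calibrated static value. Consequences
used as invariants: the group mean of calibrated statics equals the
stable value exactly; rankings of subjects and windows never change;
anchoring at the group mean is the identity. Strengths and
variabilities are computed from the **calibrated** traces; the raw
variants are a one-line change and remain computable. Calibration is
always performed separately within each group.

## Group statistics

Group differences are tested by ANCOVA (`value ~ group + FD`, OLS),
reporting the group-indicator t with the fitted model's residual degrees
of freedom. BH-FDR is applied within each measure family across the
seven systems. Symptom correlations are Pearson r reported with
`t = r√(n−2)/√(1−r²)` and df `n−2`. Relative change is
`100·(patient − control)/control`. The system permutation test shuffles
region→system labels (1000 permutations by default; a shuffle that
empties a system is redrawn), uses `|system mean − grand mean|` of the
regional changes as the statistic, and applies the add-one convention
`p = (1+#{null ≥ obs})/(1+n_perm)` so p is never zero.

## Prediction model

Regional features are ranked by univariate `F = r²(n−2)/(1−r²)`
(monotone in |r|; zero-variance features fall to the end), the top K are
selected, standardized, and fed to OLS under leave-one-out CV; accuracy
is the Pearson r between real and out-of-fold predicted scores, K is
swept (smallest K on ties), and significance comes from permuting scores
and re-running the entire selection + CV pipeline. The default
`in-fold` mode ranks, selects and standardizes on each training fold
only, so the held-out subject never leaks into selection; a `global`
mode (select once on the full sample) is provided because common
tooling composes selection outside the CV loop — the two can differ on
real data and the in-fold mode is the defensible default. Known
behavior documented rather than hidden: under a null (permuted) target,
the real-vs-predicted correlation is not tightly concentrated at zero —
it has SD ≈ 0.2 at n = 50 and a negative bias, because the held-out
subject's score is absent from the training mean (the standard
leave-one-out anticorrelation artifact). The permutation test is
unaffected (null and observed accuracies share this distribution) and
is calibrated to nominal type-I error.

## Effect decomposition

Within the patient group only (scores exist only there), each region's
measure is regressed on SANS total, SAPS total, their product (formed
from mean-centered scores, which decorrelates the interaction from the
main effects without changing its coefficient), sex, age and FD.
Rank-deficient designs are rejected naming the collinear predictor. The
SANS and SAPS coefficient maps are reduced by PCA on the two z-scored
columns (the maps are coefficients of different measures with different
scales); the first-PC scores per region form the coeffect, signed so
the loading on the SANS column is positive. The same mechanics pool the
two coeffect maps (or the two interaction maps) into an overall effect.

## Gene screen

Each gene's expression profile across regions is Pearson-correlated
with the effect map; BH-FDR is controlled in a single family across all
genes, and significant genes split into a positive and a negative set
(negating the effect map swaps the sets exactly). Constant gene columns
are excluded with a warning. Regions are treated as exchangeable
samples; no spatial-autocorrelation-preserving null is used — a known
limitation, as smooth expression gradients can inflate significance on
real atlas data. Ranked lists (by |r| within each signed set) are
exported as TSV for external GO-enrichment tooling; GO enrichment
itself is out of scope.

## Synthetic cohorts

Each subject's record alternates between two zero-mean multivariate
normal states: *integrated* (uniform correlation 0.6) and *segregated*
(0.5 within each system block, 0.05 between). The state sequence is a
two-state Markov chain with stationary integrated-state probability
(dwell) 0.6 for controls and 0.3 for the patient-like group and mean
dwell length 8 frames (16 s at TR = 2 s); defaults are 50 subjects per
group, 200 regions in 7 systems, 152 frames. Both state covariances are
verified positive semidefinite at construction, naming the offending
parameter otherwise. Demographics follow the study population the
generator emulates (ages ≈ 35 ± 9; FD 0.160 ± 0.159 mm controls vs
0.267 ± 0.215 mm patients, truncated at 0.01 — the FD confound is real
in the synthetic data, which is why ANCOVA is exercised against it).
An optional per-system correlation override for the patient group
plants a system-concentrated effect (used to validate the system
permutation test with a limbic-style alteration). Symptom dimensions
are `baseline + slope · z(feature) + noise`, clipped at zero and
rounded to integers like real clinical sums; totals are dimension sums.
Planted expression genes equal the standardized effect map plus
Gaussian noise; null genes mix a shared per-system random intercept
(spatial smoothness, avoiding an anti-conservatively independent null)
with unit noise. A ground-truth ledger (state sequences, link slopes,
planted gene identities) supports recovery tests.

What the generator does *not* emulate: hemodynamics, autocorrelated
BOLD noise, head-motion artifacts coupled to the signal, inter-subject
anatomical variability, or empirical symptom-scale distributions.
Passing tests therefore demonstrate correctness and statistical
calibration of the pipeline under its stated model, not effect sizes on
real cohorts.

## Problem sizes in tests and the acceptance script

Replicate studies run at reduced dimensionality chosen once: cohorts of
50/group with 42 regions (7 systems × 6) and static-FC components for
the power study (200 replicates); 500 null replicates for test
calibration with 500 permutations for the permutation-based tests;
prediction null calibration at n = 20 subjects, 10 features, K = 3;
effect recovery over 200 replicates of 50 patients × 30 regions; the
gene screen at 200 regions × 5000 genes with 100 planted at noise SD
0.5× signal. The decomposition oracle runs 200 random matrices with
N ∈ [8, 50]. These sizes keep every study statistically informative
while the whole suite completes in minutes on one CPU.

## Known limitations

- The permutation-test statistic (|system mean − grand mean|) and the
  FDR family definitions are reasonable choices among several; both are
  configurable at the call sites.
- The gene screen ignores spatial autocorrelation (above).
- ANCOVA covariate set is fixed to group + FD for comparisons (sex/age
  enter the effect model instead); no mixed models.
- Window tapering, partial-correlation FC and autocorrelation-adjusted
  variability are out of scope.
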