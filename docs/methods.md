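# Methods

`connmvpa` implements an inter-network functional-connectivity analysis for
a two-condition (passive viewing vs. reappraisal of negative scenes) fMRI
task, together with the psychophysiological and behavioral statistics that
accompany it, and synthetic-data generators that plant known structure so
every step can be validated quantitatively.

## The analysis chain

**Network identification.** Group-level spatial component maps (e.g. from a
group ICA) are matched against reference network maps by spatial Pearson
correlation over all voxels. A component is retained as a canonical network
when its best match reaches r >= 0.3; at the working scale 17 of 25
components are networks (DMN1-3, left/right frontoparietal, ACN1-2,
salience, limbic, REW1-2, cerebellum-basal ganglia, higher visual, visual,
sensorimotor-language, SSN1-2) and 8 are artifacts. Matching is signed by
default — a sign-flipped component fails to match — with an `absolute`
option because ICA component sign is arbitrary. Ties between references
break toward the lowest reference index and are logged.

**Dual regression.** Stage 1 solves `data ≈ mapsᵀ · tsᵀ` for the
timeseries by applying the pseudoinverse of the spatial-map matrix to each
subject's voxel x time data, giving one timeseries per group component —
artifact components included, because they are needed for cleanup. Stage 2
regresses those timeseries back into the data for subject-specific maps.
Neither stage has an intercept; inputs are demeaned along the regression
dimension (maps over voxels, timeseries over time), so on noise-free
synthetic data both stages are exact up to machine precision (verified in
the tests). Rank-deficient designs are an error that names the dependent
components.

**Network matrices.** Each timeseries is variance-normalized; artifact
timeseries are regressed out of every kept node jointly ("aggressive
cleanup", with intercept) and then discarded; the unregularized partial
correlation r_ij = -Θ_ij/√(Θ_ii Θ_jj) is computed from the inverse sample
covariance; and Fisher's r-to-z transform is applied. The default z scale is
`atanh(r)·√(T-3)` (an approximate z-statistic), because connectivity values
of magnitude ~4 are impossible as raw atanh of a partial correlation;
`raw_atanh` is available. A singular covariance raises — no silent
regularization, since the estimator is explicitly unregularized. With 17
nodes the upper triangle flattens to 136 edges in row-major order, the
feature vector for both statistical routes. The normalize-then-clean order
follows the narrative order of the upstream tooling and can be swapped via
a flag for sensitivity analysis; cleanup includes an intercept (both
choices are configurable because the upstream semantics are not pinned
down).

**Edge-wise GLM.** Per edge, the within-subject difference
(reappraise - view) is tested with a paired t. The null flips the sign of
whole subject difference vectors (preserving cross-edge dependence);
two-sided p per edge uses the add-one convention (k+1)/(n_perm+1), followed
by Benjamini-Hochberg FDR across the 136 edges (default q = 0.05, 5000
permutations). An exhaustive 2^n enumeration is available for small n, and
a max-statistic FWER alternative sits behind a flag. Note an arithmetic
constraint of the add-one convention: a single true effect can only survive
BH when `n_edges/(n_perm+1) <= q`, so scaled-down power analyses here use
40 edges with 799 permutations (floor x m = 0.05 exactly).

**Connectome MVPA.** Each subject contributes its two 136-edge vectors with
condition labels; a linear soft-margin SVM (C = 1.0, deterministic
configuration) is trained under leave-one-subject-out cross-validation, so
accuracy is always an integer count over 2·n_subjects held-out samples (at
n = 31: multiples of 1/62 — the granularity that makes 70.97% = 44/62 and
79.03% = 49/62 valid values). Significance comes from rerunning the full
LOSO under permutations that flip each subject's label pair with
probability 1/2, preserving the paired design (an unrestricted shuffle is
behind a flag). p is reported under both (k+1)/(n+1) and k/n conventions,
since published permutation p values are sometimes on the k/n convention.

**Fold-consistency feature selection.** From each fold's hyperplane, the
top round(0.10 x 136) = 14 edges by absolute coefficient are taken
(absolute, because reported meaningful edges carry both signs; a signed
option exists). Edge appearance counts across the 31 folds are compared to
Binomial(31, 14/136); the exact upper tail at the default threshold of 11
folds, computed by term-by-term summation, is 1.63e-4. We report this exact
value rather than any smaller published bound: under the stated null, the
exact tail is the defensible number. The refit on the selected edges reuses
the folds whose coefficients produced the selection and is flagged
`selection_is_circular=True` — it reproduces the original procedure and is
an optimistic estimate, not a nested-CV estimate.

**SCR scoring.** Raw 1000 Hz electrodermal traces are low-passed at 0.15 Hz
then high-passed at 0.01 Hz (2nd-order Butterworth, forward-backward so
peak latencies are unshifted; order and phase are configurable),
downsampled to 10 Hz, and scored per trial: subtract the mean of the 1 s
pre-onset baseline, trough = min over [onset, onset+1 s), peak = max over
[onset+1 s, onset+8 s] (endpoint included), amplitude = peak - trough,
floored to 0 below 0.02 uS (negative differences are "did not cross
threshold"; the alternative reading — absolute peak below 0.02 uS — is not
used), then square-root transformed. Subjects with no non-zero trial are
flagged non-responders and excluded from the condition contrast with an
explicit report. The paired contrast on per-subject condition means
delegates to the behavioral module.

**Behavioral statistics.** Paired t (df = n-1), two-tailed p from the t
survival function, and the effect size d' = |m_a - m_b| / sqrt((sd_a² +
sd_b²)/2) — the root-mean-square-SD form, the only formula consistent with
four independently printed values for this battery (two further printed
values differ in the third decimal because the printed inputs are rounded).
An item-level recognition-memory summarizer produces old/new accuracy,
per-condition hit rates and source-decision accuracy.

## Synthetic data

The generators define the validation conditions; their defaults are the
study conditions the pipeline targets: 31 subjects, 2 conditions x 284
timepoints at TR = 1 s, 25 components (17 networks + 8 artifacts), 2000
voxels (a desk-scale stand-in for a brain mask), 16 trials per condition
for SCR, 1-7 Likert ratings and percent accuracies for behavior.

- **Spatial maps** occupy contiguous voxel blocks with signed, zero-mean,
  unit-norm values; disjoint supports give exactly zero spatial correlation,
  and an `overlap` fraction shares support (and values) between neighbors
  to emulate mixed components.
- **Node timeseries** are T i.i.d. draws from N(0, Σ) where Σ⁻¹ has unit
  diagonal and off-diagonal -r_ij at the planted edges. The planted
  condition-specific partial correlations for the 15 reference edges are
  obtained from the published z-statistics as r = tanh(z/√(T-3)). If a
  requested pattern is not positive definite the generator either raises or
  shrinks all planted values by a reported factor, per flag. Artifact nodes
  are independent unit-variance noise with an optional leakage coupling for
  exercising cleanup. No hemodynamics, autocorrelation, motion or scanner
  drift are simulated: the claims under test are covariance-level, and real
  data would have fewer effective degrees of freedom than T.
- **Voxel data** follow the exact forward model mapsᵀ·tsᵀ plus i.i.d.
  Gaussian noise, so stage-1 recovery has a closed-form expected
  correlation sqrt(var/(var+σ²)) against which the tests assert. The
  default noise σ = 0.2 is calibrated so the connectivity magnitudes
  *measured* from the simulated cohort stay within ~10% of the planted
  reference values (forward noise attenuates partial correlations roughly
  by 1/(1+σ²); at σ = 1 the measured values would be less than half the
  planted ones, defeating the emulation).
- **SCR traces** are slow sinusoidal drift + white noise + one
  difference-of-exponentials bump per trial (rise 1 s, decay 6 s, peak
  ~2.15 s post-onset, peak scaled to the requested amplitude). Because any
  response peaking 2-6 s post-onset has spectral content at the 0.15 Hz
  cutoff, the filter chain attenuates bump amplitude by roughly a quarter;
  the noise-free recovery checks therefore validate the scoring steps on
  the unfiltered trace, and cohort simulations use the full chain, where
  the attenuation is proportional and leaves the condition contrast intact.
  Cohort simulations draw each subject's per-condition responsiveness from
  the planted condition means/SDs with a cross-condition trait correlation
  of 0.8, since electrodermal reactivity is a stable individual trait; the
  paired design's power depends on this shared component.
- **Behavioral tables** draw per-subject condition means as measure mean +
  subject offset + within-condition noise with the planted paired-difference
  SD, then clip to the response scale and report the clipping rate. Values
  are continuous, not ordinal draws — the analyses operate on means.

All randomness flows from one root seed through named substreams
(maps, timeseries-<condition>, scr, behavior, subject-<i>), so any stage
regenerates independently and reruns are byte-identical.

## What passing tests show — and what they do not

Planted-recovery results demonstrate the estimators and inference machinery
are correct under the generative model (i.i.d. Gaussian samples, exact
forward model, known effects). They do not certify performance on real BOLD
data, which is autocorrelated, non-stationary and motion-contaminated; the
published classification accuracies (70.97%, 79.03%) depend on the original
subject data, which is not distributed, and are therefore treated as
context, not as reproduction targets. What is reproduced exactly is every
analytic quantity computable from printed inputs: the five behavioral
two-tailed p values, three effect sizes at three decimals, the
feature-selection arithmetic (14 per fold, 10.29%), and the exact binomial
tail at the consistency threshold.

## Numerical choices and problem sizes

- Partial correlation refuses covariance condition numbers above 1e12.
- Permutation p values never report 0 (add-one convention); k/n is also
  reported for the MVPA.
- Rank ties at the selection boundary break toward the lower edge index and
  are counted in the output.
- Degenerate paired differences (zero variance) yield t = ±inf with an
  explicit flag rather than NaN.
- Demonstration sizes: the full pipeline run in `scripts/acceptance.py`
  uses the full cohort (31 subjects, 25 components, 284 timepoints) with
  5000 sign-flip permutations for the edge GLM (vectorized, cheap — and the
  add-one floor must satisfy 136/(n_perm+1) <= q for any edge to survive
  FDR) and 1000 label permutations for the MVPA (each permutation reruns
  the full LOSO fit); calibration suites use 8-12 subjects with 99-199
  permutations and 100-400 replicates; power suites use 40 edges with 799
  sign-flip permutations (see the GLM note above) and 15-100 replicates.
  These sizes were chosen so the whole validation runs on one CPU in
  minutes; all analysis defaults remain at their full values (5000
  permutations, C = 1.0, q = 0.05).

## Known limitations

- ICA estimation is out of scope; group maps are an input.
- No regularized/shrinkage connectivity estimators; short runs with many
  nodes can make the unregularized estimate noisy (T = 284 vs 17 nodes is
  comfortable; T close to n will raise).
- The circular refit is reported as such; no nested selection is provided.
- SCR scoring is trough-to-peak only — no deconvolution or tonic/phasic
  decomposition.
- The behavioral generator clips rather than models ordinal responses, so
  extreme planted means compress observed effect sizes (clipping rates are
  reported).
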