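# Methods

This note documents the models, conventions and numerical choices behind
`funcgrad`, the way the synthetic cohort generator emulates a dopamine
ON/OFF resting-state study, and what the tests do and do not establish
about real data.

## 1. From timeseries to gradients

**Connectivity.** Each scan is a time × parcel matrix (400 cortical
parcels with Yeo-7 network labels by default). Parcel timeseries are
z-scored and the functional connectivity (FC) matrix is the parcel ×
parcel Pearson correlation. Constant parcels are a hard error — they mean
the input was not a valid BOLD extraction.

**Sparsification.** Each FC row keeps its top 10% of off-diagonal entries
by *signed* value (`k = round(0.10 · (P−1))`, so 40 of 399 at P = 400);
everything else, including the diagonal, is zeroed. Selecting by signed
value discards strong negative correlations, the convention of the
gradient toolboxes this pipeline is compatible with. Ties at the cutoff go
to the lower parcel index (stable argsort), making the operation
deterministic. The diagonal is excluded from selection because a
self-correlation of 1 would otherwise always survive; at P = 400 the two
conventions (10% of 400 vs. of 399) give the same k = 40, and the
off-diagonal convention fixes the behaviour at every other P.

**Affinity.** Similarity between connectivity profiles is the cosine of
the angle between sparsified FC rows. Negative cosines (possible because
retained entries can be negative) are clipped to 0 — the diffusion
operator requires a nonnegative affinity — and the number of clipped
entries is logged.

**Diffusion-map embedding.** With affinity `W`, degree `D = diag(W·1)`
and anisotropy parameter `α` (default 0.5):

    W' = D^(−α) W D^(−α),   P = D'^(−1) W'   (D' the degree of W')

The spectrum of `P` is computed through the symmetric conjugate
`D'^(−1/2) W' D'^(−1/2)` (dense `eigh` up to P = 512, Lanczos beyond;
tolerance 1e−10). The trivial constant eigenvector (λ = 1) is dropped;
gradient *i* is the *i*-th non-trivial right eigenvector, unit-normalized
and scaled by `λᵢ/(1−λᵢ)` — the diffusion-time-0 convention of the
ecosystem's gradient toolboxes. `α = 0.5` balances geometry against
sampling density and is the community default for FC gradients. A
disconnected affinity graph is an error that reports component sizes:
embedding a disconnected operator silently produces indicator-like
components. Variance explained per gradient is `λᵢ / Σλ` over the
computed components (10 by default).

**Template, alignment and labeling.** The group template embeds the
element-wise mean FC matrix of *all* scans (both conditions plus
controls), with the identical threshold/affinity recipe — the recipe is
described explicitly only for the average matrix in the source analyses,
and applying the same recipe per scan is logged as this package's
assumption. Individual gradients are mapped onto the template by
orthogonal Procrustes (rotation/reflection only; no scaling or
translation; `scipy.linalg.orthogonal_procrustes`), aligning 10
components; residuals before/after are recorded, and alignment can only
decrease the Frobenius residual. The first three aligned components are
labeled G1/G2/G3 against reference axes (in practice the template's
leading components, or any user-supplied canonical maps): greedy matching
by maximal |Spearman ρ| without replacement, sign flipped so ρ > 0. Ties
within 1e−6 that compete for the same component or axis are an error —
a silent arbitrary choice would corrupt every downstream comparison.
Before labeling, component sign is meaningless and tests compare up to
sign.

## 2. The 3-D manifold and dispersion

The manifold is exactly the space of the labeled G1/G2/G3 scores.
Network *centres* are coordinate-wise medians (even counts: mean of the
two middle values). *Between-network dispersion* is the Euclidean
distance between two centres; *within-network dispersion* is the sum of
squared distances of a network's parcels to its centre. The source
analyses state the median explicitly only for between-network centres; we
use the median for the within-network centre too, for consistency — the
choice is flagged, and because the mean (not the median) minimizes the
sum of squared distances, median-centred within-dispersion is ≥ the
mean-centred value (tested as an invariant rather than asserting any
mean-based decomposition). Distribution descriptors per gradient are the
range and Sarle's bimodality coefficient
`(g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3)))` with bias-corrected skewness g₁
and excess kurtosis g₂ (≈ 1/3 for a normal sample, → 1 for a balanced
two-point mixture; undefined for a constant vector, which is flagged).

## 3. Inference

**Paired sign-flip permutation.** The observed statistic is the paired t
of ON−OFF differences; the null flips each subject's difference sign
independently. When `2ⁿ ≤ n_perm` all flips are enumerated and plain
proportions reported; otherwise Monte Carlo with the add-one rule
(`p = (1+hits)/(B+1)`, so min p = 1/(B+1) and p = 0 is impossible).
Two-sided throughout. Degenerate flipped samples (zero variance) give
t = ±∞, handled explicitly; all-zero differences give t = 0, p = 1 with a
warning. Sign draws come from a counter-based Philox generator keyed by
the seed, with the whole draw matrix generated in permutation-index
order, so results do not depend on any execution layout.

**Max-statistic FWE.** Families (21 between-network pairs; 7 within
metrics; 21 network × gradient mean shifts; P regions per gradient) share
one set of sign flips; each metric's `p_fwe` compares its observed |t| to
the permutation distribution of the family maximum |t|. This controls
family-wise error under the exchangeability of paired sign flips while
respecting the dependence among metrics, and guarantees
`p_fwe ≥ p_uncorrected`. Network shift and regional tests report both
uncorrected and FWE values — the source analyses appear to use
uncorrected thresholds for regional counts, and both are emitted rather
than asserting either as "the" convention.

**Distribution comparisons.** Two-sample Kolmogorov–Smirnov per gradient
with asymptotic p-values, BH-FDR across the three gradients. The samples
pool region-level scores across subjects per condition (n_pairs × P
points per sample) — the only pooling unit that can produce the small D
values these analyses report; this choice is flagged as ours.

**State × dose mixed model.** `value ~ state · dose + (1 | subject)`,
REML, state coded OFF = 0 / ON = 1, dose z-scored across subjects before
the interaction (coefficients are per dose-SD; the per-mg/day value is
also reported). Fixed effects come from `statsmodels` MixedLM. The
interaction F-test uses an exact identity of the balanced paired design:
with one ON and one OFF value per subject, the REML/GLS estimate of the
interaction equals the OLS slope of the within-subject difference on
dose, with denominator df = n − 2 — which is also the Satterthwaite df in
this balanced case. A design with all doses identical is an explicit
error. BH-FDR is applied across tested metrics.

**Δ maps and spin tests.** Δ is the per-region mean ON−OFF change of a
labeled gradient. Associations between Δ and annotation maps
(e.g. regional gene expression) use Spearman ρ with a spin-permutation
null: a Haar-uniform rotation of one hemisphere's spherical centroids,
its x-mirrored counterpart on the other hemisphere, and
nearest-neighbour re-assignment within hemisphere (duplicates allowed;
identity excluded). The *annotation* map is rotated; the data map stays
fixed. The spin null preserves the map's spatial autocorrelation, which
naive value permutation destroys — naive permutation is anticonservative
for smooth maps, and the acceptance suite demonstrates exactly this
contrast. Meta-analytic term maps are ranked by Spearman ρ (top-k
positive/negative) with no significance claims.

## 4. The synthetic cohort generator

The generator emulates the study conditions end to end with no imaging
data:

- **Cohort shape** (defaults): 27 ON/OFF subject pairs + 19 single-scan
  controls; 140 timepoints × 400 parcels; Schaefer-400/Yeo-7 network
  sizes (61, 77, 46, 47, 26, 52, 91).
- **Doses**: daily dopamine dose equivalents drawn from
  N(680.28, 404.79²) mg/day (the cohort's reported mean/SD), truncated at
  0, z-scored within cohort before scaling the effect.
- **Parcel scheme**: networks occupy mirrored spherical patches
  (angular jitter 0.25 rad around fixed patch directions), so network
  maps are spatially autocorrelated and spin nulls are meaningful.
- **Target covariance**: block structure with `within_r = 0.30` inside
  networks and `between_r = 0.10` across (realistic magnitudes for
  band-passed parcel FC), plus a distance-decaying component
  `0.5 · exp(−d/0.4)` centered within every network-block pair. The
  spatial component matters: real cortical FC falls off smoothly with
  distance, and without it the thresholded affinity graph of an ideal
  block matrix is disconnected (each network's profile has disjoint
  support). Centering per block pair keeps all block-mean correlations at
  their nominal values.
- **Planted effect**: in the ON condition the between-block correlation
  of (VIS, DAN) and (VIS, VAN) is reduced by
  `effect_size · (1 + dose_interaction · dose_z)` — segregation that
  grows with dose. Subject random effects perturb all between-network
  correlations (SD 0.02) and are shared between a subject's ON and OFF
  scans, which is what makes the paired design informative.
- **PSD repair**: perturbed matrices are projected to the nearest PSD
  correlation matrix (eigenvalue clipping at 0, tolerance 1e−10,
  re-standardized to unit diagonal).
- **Timeseries**: i.i.d. multivariate-normal draws from the target
  correlation. No temporal autocorrelation, hemodynamics, motion or
  scanner noise are simulated: every downstream statistic is a function
  of the Pearson FC only, and the inputs the real pipeline consumes are
  already denoised and band-passed.
- **Annotation maps**: Gaussian-process fields on the sphere with
  covariance `exp(−d/smoothness)`, z-scored — stand-ins for regional
  gene-expression or meta-analytic maps.

**Effect-size calibration.** The magnitude of the ON/OFF dispersion
difference has no published scale, so the planted effect is calibrated
internally by a pilot grid over `effect_size` × `dose_interaction`
(detection = both effect-pair metrics FWE-significant at 0.05, power
target 0.8 over seeds). The calibrated values are `effect_size = 0.19`,
`dose_interaction = 0.2`. Two honest observations from the pilot, kept
rather than engineered away: (i) planting between-network segregation
leaks mildly into within-network dispersion (mean within-network t of
roughly −1 to −1.4 for the involved networks at these effect sizes) —
changing a network's connectivity profile necessarily reshapes its own
spread in the manifold, so "within stays null" holds only approximately
at detectable effect sizes; (ii) a larger `dose_interaction` spreads
per-subject effects and *reduces* detection power while making the
pipeline-level interaction test stronger — 0.2 favours detection power,
so per-run interaction F values on pipeline output are often modest even
though the model-level interaction recovery is unbiased.

## 5. What the tests show (and what they do not)

The acceptance suite verifies: spectral agreement of the embedding with
an independently coded dense implementation (50 random affinities,
1e−8); perfect block recovery (silhouette 1 on gradient 1 of a 3-block
connectome); exact hand-computed dispersion values; exact enumeration of
the sign-flip null (p = 2/32 for five equal positive differences);
empirical FWE of the max-statistic family ≤ 0.07 under a correlated
global null (500 cohorts); spin-test type-I within [0.025, 0.075] for
independent smooth maps while naive permutation exceeds 0.10; unbiased
interaction recovery (200 cohorts, within 10%) with nominal null level;
end-to-end detection of the planted segregation with power > 0.8 and a
near-null within-network family; and strict monotonicity of the mean
ON−OFF effect-pair dispersion over the effect grid {0, 0.05, 0.10, 0.15}
(50 seeds per level).

Problem sizes used by the heavier checks are a deliberate scaling of the
study conditions: the FWE calibration simulates difference matrices
directly (27 × 21, 500 permutations × 500 cohorts); the spin calibration
uses 200 replicates × 300 rotations on the 400-parcel sphere; the
end-to-end power check runs 12 full cohorts at the default study shape
with 500 permutations; the monotonicity check runs 10-pair, 140-parcel
cohorts (20 parcels per network) for 4 × 50 runs. The full default
configuration (1000 permutations/rotations) is exercised once by
`scripts/acceptance.py`.

None of this certifies behaviour on real fMRI: the generator's
multivariate-normal world has no temporal autocorrelation, no motion
artefacts, no inter-site variability, and its network covariance is far
more homogeneous than cortex. What passing tests *do* establish is that
the machinery is numerically correct, calibrated under its own nulls, and
able to recover effects of the planted kind at realistic sample sizes.

## 6. Known limitations

- Gradient labeling against the template's own leading components is
  circular by construction in the synthetic setting; with real data the
  reference axes should be canonical published maps.
- The within/between dispersion leak described above means the generator
  cannot plant an arbitrarily strong between-network effect while keeping
  within-network metrics exactly null.
- The spin test operates at parcel level (duplicates allowed), the
  standard compromise; variogram-matched surrogates are out of scope.
- The mixed-model F test's exact-df shortcut assumes the balanced paired
  design; unbalanced data are rejected rather than approximated.
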