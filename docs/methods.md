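# Methods

This note documents the models, estimators and numerical choices behind
`dmnstab`, and what the synthetic cohorts do and do not emulate.

## Network parameterization

The network is the four-region core DMN: precuneus (PRC), medial prefrontal
cortex (mPFC), left and right inferior parietal cortex (lIPC, rIPC), in
that fixed order. Directed connectivity lives in a 4×4 matrix `A` with the
column-to-row convention: `A[t, s]` is the influence of region `s` on the
rate of change of region `t`, in Hz. Diagonal entries are unitless
log-scale parameters `a` mapped to effective self-connections
`s_ii = −0.5·exp(a)` Hz, so self-influence is always inhibitory and `a = 0`
corresponds to −0.5 Hz. All modules share one flattening of the 16
parameters: the 12 off-diagonal entries in target-major order, then the 4
diagonal log-scale parameters.

Priors (`network.default_session_prior`) are shrinkage priors: extrinsic
connections ~ N(0, 1/64) Hz², log-scale self parameters ~ N(0, 1/256).
These are sign-agnostic but preclude extreme values; the tighter self prior
reflects cortical gain control.

## Synthetic cohorts (`cohort`)

A cohort is generated hierarchically:

* **Group**: a left/right-symmetric baseline pattern with bilateral IPC
  driving the medial regions and each other (0.20–0.25 Hz), weak
  medial-to-lateral connections, and mild mPFC→IPC inhibition (−0.10 Hz).
  Symmetry at baseline means any asymmetry in the cohort is exactly the
  injected dominance effect.
* **Subject** = group + dominance offset + i.i.d. Gaussian effect per
  parameter (sd `between_subject_sd`, halved for the log-scale self
  parameters to mirror the 4× tighter self prior).
* **Session** = subject + i.i.d. Gaussian effect (sd `between_session_sd`),
  optionally with the dominance offset flipped to the contralateral IPC
  with probability `flip_probability` (the mechanism behind real session
  flips is unknown; this is an explicit knob, default 0).

Each subject is left-dominant with probability 0.625 (10 of 16 in the
reference cohort design), right-dominant otherwise, with an optional
`symmetric_probability` for subjects without dominance. The dominance
offset has three parts, each anchored to a reported feature of real
lateralized DMN cohorts:

| component | default | expresses |
|---|---|---|
| `asymmetry_magnitude` | +0.3 Hz on the dominant IPC's 3 efferents | a subject-level left-minus-right efferent difference of 0.6 Hz between dominance groups, the scale reported for real subjects |
| `self_offset` | −0.3 (log-scale) on the dominant IPC's self parameter | the dominant IPC is the least self-inhibited region in almost all lateralized subjects |
| `afferent_offset` | −0.15 Hz on the non-dominant IPC's inputs from PRC and mPFC | the non-dominant IPC is mildly inhibited by medial regions once dominance is accounted for |

`between_subject_sd` defaults to 0.10 Hz, calibrated so the dominance
component explains ≈ 60–65% of between-subject parameter variance in a
16-subject cohort — the regime in which the first principal component
across subjects is the asymmetry pattern, as reported for real data. Under
these defaults a mixed cohort shows mean between-subject correlations of
roughly 0.7 (left/right order) rising to ≈ 0.9 after dominance reordering.
`between_session_sd` defaults to 0.1 Hz, which makes ~95–99% of sessions
significantly asymmetric at the 90% criterion and leaves realistic
session-to-session sign variability in the weaker connections.

Every sampled matrix must be dynamically stable (all eigenvalues of the
effective matrix with negative real part); draws are rejection-sampled with
a cap of 1000 retries, and exceeding the cap raises an error identifying
the spec as over-dispersed.

Session measurement uncertainty is emulated by
`emit_session_posteriors`: Gaussian posteriors with mean = session matrix
+ N(0, sd²) noise and diagonal covariance sd²·I (default sd 0.05 Hz).
These are *measurement densities*, not prior-shrunk posteriors — which is
why the empirical-prior pass treats their full prior as non-informative
(below).

What the generator does **not** emulate: scanner/sequence differences
between datasets, physiological confounds, non-Gaussian or heavy-tailed
random effects, parameter correlations within a level, temporal drift
across sessions, and any image-level artifacts. Tests passing on these
cohorts therefore validate the *estimators and statistics*, not robustness
of the method to realistic fMRI artifacts.

## Cross-spectral model and inversion (`spectral`)

Neuronal dynamics are linear: `dx/dt = A_eff x + v(t)`, with fluctuations
`v` given a power-law spectral density `g_v(w) = alpha_v · w^(−beta_v)`
(angular frequency, two-sided density per Hz; defaults alpha_v = 1,
beta_v = 1). Each region's activity passes through the first-order
linearization of the canonical Balloon hemodynamic model around its fixed
point — neurovascular kinetics (signal decay κ = 0.64 s⁻¹, feedback
γ = 0.32 s⁻¹), transit time τ = 2 s, stiffness α = 0.32, resting oxygen
extraction E₀ = 0.4, V₀ = 0.04, classic (k1, k2, k3) BOLD coefficients —
yielding a rational transfer function H(w). Observation noise enters as a
flat (beta_e = 0) spectral density alpha_e = 0.05 on the diagonal, giving
an in-band spectral SNR of roughly 5–20. The predicted cross-spectral
density on the analysis band 0.0078–0.1 Hz is

    S(f) = T(w) G_v(w) T(w)^H + G_e(w) I,   T(w) = H(w) (iwI − A_eff)^{-1}.

Time series are synthesized spectrally (complex Gaussian Fourier
coefficients with the model covariance per DFT frequency), so Welch
estimates converge to `predict_csd` by construction; the Welch estimator
returns two-sided densities (half of scipy's one-sided convention) with
segment length `min(n/2, max(64, n/4))`.

**Inversion** is MAP + Laplace, deliberately simpler than variational
schemes: the 16 connectivity parameters plus 4 spectral nuisance
parameters (log alpha_v, beta_v, log alpha_e, beta_e; shared across
regions, prior variance 1/4 around the defaults) are fit by Gauss–Newton
(`scipy.optimize.least_squares`) on the stacked real and imaginary parts
of the cross spectra, amplitude-normalized per entry by
`1/sqrt(S_ii S_jj)` so steep low-frequency autospectra do not dominate.
The feature precision λ is re-estimated from the residual between
optimizer rounds (up to 3 rounds, capped at 1e12 so a perfect fit cannot
divide by zero). Multi-start (default 4 seeded starts spread 0.5 prior-sd
around the prior mean, best objective wins) guards against local optima;
the posterior covariance is the Gauss–Newton Laplace approximation at the
optimum, marginalized to the 16 connectivity parameters. Zero prior
variance clamps a parameter at its prior mean. Explained variance is
computed on the weighted feature vector. Under the generator defaults
this inversion recovers extrinsic connectivity with mean truth–estimate
correlation ≈ 0.85–0.89 at 256 scans (TR 2 s), and RMSE decreases
monotonically from 64 to 512 scans.

The outputs are *structurally*, not numerically, comparable to SPM's
spectral DCM: all downstream stages consume only Gaussian posteriors, so
either backend fits the contract.

## Hierarchy (`hierarchy`)

Sessions are carried to subject level (and subjects to group level) under

    y_i ~ N(X_i β, Σ_i + Γ),   β ~ N(0, C0),

with `y_i, Σ_i` a unit's posterior moments, Γ a diagonal per-parameter
between-unit covariance (a separate precision component per connection),
and C0 the session-level prior covariance. The expected between-unit
variability is a fixed fraction of the within-level prior: Γ is anchored at
`prior_ratio·C0` (default 1/16) through a weak scaled-inverse-chi-square
regularizer (strength ν = 1 pseudo-unit) in the EM M-step, which also keeps
the variance updates away from degenerate optima. EM alternates exact
Gaussian E-steps (posterior over β and the unit-level effects) with the Γ
update, to tolerance 1e−8 on Γ, cap 500 iterations. The default design is
a single column of ones (average connectivity); general designs are
accepted but covariate modelling is out of scope. A `flat_prior` variant
drops the prior on β — used for single-unit averaging and for calibration
checks of the estimator itself, since the shrinkage prior deliberately
biases large baseline values toward zero. The free-energy surrogate is the
Gaussian marginal likelihood of the hierarchy (β integrated out under a
proper prior, profiled under a flat one), for relative comparisons only.

**Bayesian model reduction** is the closed-form Gaussian identity: with
posterior precision P, full-prior precision P0 and reduced-prior precision
Pr, the reduced posterior has precision `Pq = P + Pr − P0`, mean
`Pq^{-1}(Pμ + Pr m_r − P0 m_0)`, and the log-evidence change follows from
the corresponding Gaussian integrals. A non-positive-definite `Pq` raises
an error naming the prior pair incompatible. `prior_full=None` treats the
posterior as a pure measurement density (P0 = 0) — the correct reading for
the synthetic session posteriors. Zero-variance coordinates of the reduced
prior clamp exactly.

The **empirical-prior pass** reduces each session posterior to an
empirical prior centred on its subject's mean with variance = estimated
between-session Γ plus the subject-mean uncertainty (and subjects likewise
toward the group mean, with their actual C0 prior as the full prior; an
explicit prior's empirical replacement is capped at the original prior
variance so it is never less informative). Under the generator defaults
the pass shrinks session variances, moves sessions toward their subject
mean, and raises mean within-subject correlation (≈ 0.87 → 0.91 on the
default cohort), mirroring the reliability gain reported for empirical BMR
on real data.

## Stability metrics (`stability`)

* **Asymmetry index**: the linear contrast c = (mean of the 3 lIPC
  efferents) − (mean of the 3 rIPC efferents), in Hz; "outgoing
  connectivity" excludes self-connections. The posterior probability is
  the larger of P(c·θ > 0) and P(c·θ < 0) under the Gaussian posterior
  (direction-agnostic significance, direction read from the sign);
  dominance requires it to reach the criterion (default 0.90).
* **Dominance reordering** exchanges the lIPC/rIPC rows and columns — a
  symmetric permutation of the 16-vector applied jointly to mean and
  covariance — for right-dominant units; a unit without dominance cannot
  be reordered and must be excluded.
* **Pairwise consistency**: Pearson correlation (Spearman available)
  between vectorised matrices for all unordered pairs. All 16 parameters
  are included by default (`extrinsic_only` switches to the 12 extrinsic
  ones); the choice is exposed because the convention is genuinely open.
* **Sign stability**: per extrinsic connection, each unit is classified
  positive/negative when the marginal posterior probability of that sign
  reaches the criterion, else non-significant; fractions sum to 1, and a
  threshold query returns connections with the same sign in at least a
  given fraction (e.g. 75%) of units.
* **PCA**: covariance PCA (centered, unstandardized — the parameters share
  comparable scales) of unit-by-parameter matrices; the component sign is
  fixed so the largest-magnitude loading is positive. The asymmetric-flag
  rule: at least two of the three highest loadings on one IPC's efferents
  and at least two of the three lowest on the contralateral IPC's
  efferents.

## Randomization and binomial inference (`inference`)

All randomization p-values use the add-one rule
`p = (1 + #{null ≥ observed}) / (1 + n_rand)` (one-sided; the alternative
is always "reordering/processing increases consistency") and are exactly
reproducible under a seed. Including the identity permutation makes the
tests marginally conservative — visible as a slight excess of large
p-values in calibration runs — which is the standard, valid choice.

* **Swap null**: the observed effect is the mean pairwise correlation
  after dominance reordering minus before. Each randomization swaps, per
  unit with probability ½, the efferent-pair entries of the two IPCs
  (lIPC→PRC ↔ rIPC→PRC, lIPC→mPFC ↔ rIPC→mPFC, lIPC→rIPC ↔ rIPC→lIPC;
  afferents and self-connections untouched — a `swap_self` flag extends
  the swap since the original procedure's scope is not fully specified),
  re-derives dominance from the permuted matrix, reorders, and records the
  same difference. Between-subject and within-subject (per subject over
  sessions, BH-corrected across subjects) variants share the machinery.
  Bernoulli(½) per-unit swaps with a few thousand draws stand in for the
  2^n swap group; the sampled p matches exhaustive enumeration within
  Monte-Carlo error (tested at n = 8).
* **Paired label null**: mean(b) − mean(a) against pairwise label flips.
* **Binomial stability**: sessions without significant asymmetry are
  discarded (chance level exactly 50%); the count of sessions matching the
  subject's dominance is tested with the exact two-sided binomial p-value
  `P(X ≥ max(k, n−k)) + P(X ≤ min(k, n−k))`, BH-corrected across tested
  subjects (subjects without dominance excluded). The published
  per-subject session counts and effect percentages ship as package data;
  the matching count is recovered by nearest-integer rounding of
  `effect × n`, verified consistent for all 16 rows, and the recomputed
  table matches the printed p-values at 3 decimals (one value, 0.1125, is
  an exact rounding tie).

Power note: the swap null retains whatever part of the dominance signature
the reordering restores (the efferents), so its power comes entirely from
the non-efferent components (self, afferent). Near-unilateral cohorts
(minority dominance group ≤ 4 of 16) leave the null almost nothing to
destroy and the test is intrinsically weak there; analyses of the
reordering gain therefore condition on a genuinely mixed split (minority
≥ 5 of 16, as in the reference design's 10/6).

## QC (`qc`)

Framewise displacement is the sum of absolute backward differences of the
three translations plus the three rotations converted at a 50 mm head
radius (small-angle); the formula and radius are configurable since the
convention varies. The effective-parameter count thresholds the univariate
Gaussian KL divergence of each marginal posterior from its prior at 0.5
nats (configurable; the reference pipeline does not state its threshold).
The principal eigenvariate is the first right singular vector of the
voxels-by-time matrix, scaled by `s1/sqrt(n_voxels)` and sign-fixed to
correlate positively with the voxel set. The stepwise alpha rule uses a
fixed 0.05 below 200 scans and otherwise steps through 0.001 → 0.01 → 0.05
until every region has a surviving voxel. The session gate is the strict
conjunction: explained variance > 60%, at least one estimated effect
> 1/8 Hz (extrinsic absolute values and self deviations from −0.5 Hz), at
least one effective parameter, max FD < 1.5 mm, and voxel detection at
alpha ≤ 0.05; failures are enumerated by name.

## Problem sizes and determinism

Simulation-heavy checks use desk-scale sizes chosen to keep the full suite
fast while leaving comfortable statistical margins: 20 replicates per scan
count for parameter recovery, 50 cohorts for the reordering-gain power
check, 400 reduced-draw replicates for calibration. Every stochastic
component takes an explicit integer seed; identical seeds give
bit-identical cohorts, series, nulls and fits.

## Known limitations

- The inversion is MAP + Laplace on a simplified generative model; its
  posterior *uncertainties* are only approximate (Gauss–Newton curvature,
  empirical λ), and its outputs should not be compared numerically to
  SPM's spectral DCM.
- Empirical-Bayes group intervals ignore the uncertainty of the estimated
  random-effects variances and are slightly overconfident at small n.
- The generator's dominance effect is additive and homogeneous across
  subjects; real lateralization is more idiosyncratic.
- No covariate designs beyond the intercept column; no model-space search
  beyond the empirical-prior pass; no image-level processing (GSR and
  ROI-size questions are supported only as generic paired comparisons of
  posterior sets).
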