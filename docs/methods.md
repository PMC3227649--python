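# Methods

This note documents the models, estimators, numerical conventions and design
choices behind `tfspm`, and what the synthetic-data generator does and does
not emulate.

## Synthetic data generator

**Design.** Each subject performs `4 × identities × repetitions + n_targets`
trials (defaults 14 × 3 + 15 = 183) in randomized order: a 500 ms fixation
cross, a first stimulus for 500 ms, a second stimulus for 1000 ms whose
direction reverses the first, and a uniform 2000–5000 ms intertrial
interval. The four non-target condition pairs cross stimulus type
(eyes/mosaic) with first direction (averted/straight). Target trials carry no
condition content and are excluded from analysis; they exist only so the
trial bookkeeping (183/subject) matches the emulated paradigm.

**Signals.** Six channels per subject (left/right amygdala, left/right
white matter, horizontal/vertical EOG) at 1000 Hz. The field-potential
background is zero-mean Gaussian noise with power spectrum ∝ f^−α (default
α = 1, flat below 1 Hz), band-limited to the 0.5–120 Hz acquisition band and
normalized to unit RMS, synthesized by frequency-domain shaping of white
noise. Every (subject, channel) pair draws from its own deterministic
substream keyed by `(seed, subject, channel)`, so datasets are byte-identical
across runs and channels are independent.

**Bursts.** Condition effects are Gaussian-windowed cosine bursts with
envelope σ_t = n_cycles / (2π f), deliberately matched to the seven-cycle
analysis wavelet so the injected and measured loci coincide. The
`paper_mimic` preset injects eyes-specific, direction-independent bursts into
the amygdala channels only: 200 ms / 44 Hz after the first stimulus and
285 ms / 40 Hz after the second. White-matter channels never receive bursts,
preserving the spatial-specificity control.

**Burst amplitude = 0.5 × background RMS (calibrated constant).** This is a
free parameter of the emulation, not an estimate of any real signal-to-noise
ratio. It was calibrated once so that the full pipeline both detects a
significant cluster and recovers the injected locus within the smoothing
kernel's scale (±30 ms, ±4 Hz) in the large majority of seeds at 6 subjects
× 42 trials/condition, and then frozen. At this amplitude the pipeline's
peak Z is considerably larger than what a 6-subject clinical recording would
produce; the generator's purpose is parameter recovery, not effect-size
realism.

**EOG.** White-noise channels plus ocular transients at Poisson-distributed
times (expected `eog_artifact_rate` events per trial): saccade-like smoothed
boxcar steps (~300 ms, alternating sign) on the horizontal channel and
blink-like Gaussian deflections (σ = 60 ms) on the vertical channel. EOG
substreams are independent of the field-potential channels, so the null
hypothesis of the contamination tests is true by construction.

**What the generator does not emulate.** Real epileptiform or movement
artifacts (the background is Gaussian), electrode cross-talk and volume
conduction, line noise (the acquisition notch is moot), trial-to-trial
amplitude/latency jitter of the evoked response, and any behavioral
structure. Consequently, passing tests demonstrate that the *pipeline*
recovers what was injected under its own assumptions — not that those
assumptions hold for clinical recordings. One visible consequence: the
±3 SD amplitude screen rejects ~45–50 % of purely Gaussian epochs (an epoch
has ~300 near-independent samples, so some sample exceeds 3 SD often),
whereas clinical studies report ~12 % driven by genuinely heavy-tailed
artifacts. The screen's decision rule, not its rejection rate, is the tested
contract, and rejection is condition-independent under the null (verified).

## Preprocessing conventions

- Resampling is polyphase with linear-extension padding (`resample_poly`,
  `padtype="line"`); output length is `round(n · rate_out/rate_in)`.
  Epoch-then-resample and resample-then-epoch agree exactly outside the
  filter's ~50 ms startup region; the pipeline always resamples the
  continuous recording first, so epochs never contain startup transients.
- Epoching: onset sample = floor(onset_ms × 0.2) on the 200 Hz grid; epoch
  sample i covers −500 + 5·i ms; presentation 2 epochs are locked to the
  second-stimulus onset (first onset + 500 ms).
- Artifact screen: the mean and SD are taken over **all samples of all
  epochs** of an electrode (per subject, per presentation) — the most literal
  reading of a "total mean ± 3 SD" criterion — and an epoch is rejected iff
  any sample leaves that band. SD = 0 rejects nothing. Because the moments
  are recomputed from the full data each call, the operation is idempotent.
  Both presentations are screened separately.

## Time–frequency decomposition

- Seven-cycle complex Morlet wavelets, L2 (unit-energy) normalized, on an
  integer 4–60 Hz grid; at 200 Hz the native time step is 5 ms. Both grids
  are finer than the smoothing kernel, so no information is lost to the grid.
- Convolution is FFT-based with zero padding over the full 1500 ms epoch.
  The statistical window (0–500 ms) keeps epoch-edge bias negligible for
  f ≥ 8 Hz; for 4–8 Hz cells (wavelet support up to ±875 ms) residual edge
  contamination is accepted and noted here rather than masked.
- Log transform with floor `1e-12 × max(power)` of the map batch: prevents
  −∞ at exact zeros while preserving order above the floor.
- Smoothing: separable Gaussian, σ = FWHM/√(8 ln 2) per axis, with
  **reflect** boundaries. Reflection maps a constant map to itself and
  conserves the global mean exactly; per-edge kernel renormalization, a
  plausible alternative, does neither in general.
- Batch maps are computed in single precision (the downstream GLM and
  inference run in double); the unit-level API defaults to double.

## GLM

- Fixed-effects pooling: all retained trials of all subjects (and both
  amygdala channels, giving the laterality factor) enter one model per cell.
  Cell-means coding of the 2×2×2 condition factors plus sum-to-zero subject
  blocks (S − 1 columns); in balanced designs the blocks are exactly
  orthogonal to the cell columns, and contrasts on cell means are invariant
  to the block-coding basis (tested). Covariates are mean-centered scalar
  per-trial columns.
- Contrasts: each involved factor coded +1/−1 (first level positive), cell
  weight = product of codes, scaled so a main effect is a difference of
  condition means. Inference on eyes > mosaics is one-sided by default
  (upper-tail height threshold); interactions use the same ±1 machinery.
- Non-sphericity: the error covariance is modeled as diagonal with one
  variance per stimulus type, pooled over all cells of the analysis window —
  the failure mode this guards against is unequal error variance between
  eyes and mosaic trials. Estimation is fixed-point ReML: each group
  variance is rescaled by observed/expected pooled residual power under the
  current GLS fit, where the expectation accounts for the residual-forming
  projection; convergence tolerance 1e-6 on log variances, hard error after
  100 iterations. Rows are then whitened by 1/σ_group and the model refit;
  effective degrees of freedom come from the Satterthwaite ratio
  tr(RV)²/tr(RVRV) on the whitened system. An OLS fallback is a config flag.
- Adjusted maps (display output) residualize the data against the intercept
  and subject indicators before averaging per condition; effect sizes are
  means over a 30 ms × 6 Hz rectangle centered on a focus, clipped at map
  edges.

## Random-field inference

- T→Z by probability matching, Z = Φ⁻¹(F_t(T; df)), evaluated through
  survival functions on the smaller tail so |T| up to ~50 stays finite.
- Smoothness from standardized residuals: each residual map is divided by
  the per-cell root sum of squares; per-axis curvature λ_j is the summed
  squared **forward difference** (central differences would halve the
  apparent roughness of a white field); FWHM_j = sqrt(4 ln 2 / λ_j);
  resels-per-cell RPV = sqrt(λ_t λ_f)/(4 ln 2), total resel count
  R = Σ RPV. The analysis window is restricted to 0–500 ms × 4–60 Hz before
  smoothness estimation and inference.
- Clusters: 4-connected excursions above u = Φ⁻¹(1 − 0.01). Peak ties break
  to the smallest time, then smallest frequency.
- Corrected peak p = 1 − exp(−E[EC](z_peak)) with the three 2D
  Gaussian-field EC densities and resel counts (R₀ = 1, R₁ from the window
  edges in FWHM units, R₂ = Σ RPV).
- Corrected extent p: cluster extents are measured in resels (Σ RPV over the
  cluster — the non-stationary correction; under uniform smoothness this
  reduces exactly to k × RPV). In 2D the cluster-size distribution is
  exponential in resel units with mean E[n] = R·Φ(−u)/E[m], so
  p_unc = exp(−k_resels/E[n]) and p_corr = 1 − exp(−E[m]·p_unc). Refined
  non-stationary cluster-size distributions are out of scope; the resel
  route is validated against the permutation oracle instead.
- Corrected p-values are floored at their uncorrected counterparts: when the
  expected cluster count in a small search region drops below 1, the raw
  Poisson-clumping formula would otherwise undercut the uncorrected p.
- Conjunction (global null): cell-wise minimum of per-subject Z maps (each
  from a per-subject GLM with the same contrast), with the expected EC of
  the intersection of K independent excursion sets obtained by the
  upper-triangular Toeplitz matrix-power construction over the EC densities;
  expected suprathreshold resels R·Φ(−u)^K (stationary approximation).
- Permutation oracle: condition labels permuted within subject; corrected
  p = (1 + #{null ≥ observed})/(n_perm + 1) for both the max statistic and
  the max resel extent, bounding the attainable resolution at 1/(n_perm+1).

Calibration measured by the test suite: the cluster-extent FWER over 200
effect-free reduced datasets stays below the nominal 0.05 (typically
0.02–0.05 — 2D Gaussian RFT at this smoothness is mildly conservative), and
RFT corrected peak p tracks the Monte-Carlo max-statistic p with rank
correlation > 0.9 and agrees within a factor of 3 for p ∈ [0.01, 0.5].

## EOG controls

- Correlations: per-trial Pearson r between matched amygdala and EOG epochs
  over the 0–500 ms analysis window (configurable), raw and after 30–60 Hz
  zero-phase Butterworth filtering; |r| clipped to 1 − 1e-10 before
  Fisher's z; per-subject mean z; one-sample t across subjects
  (df = n_subjects − 1). Constant traces are skipped and counted.
- Covariates: mean analytic-signal (Hilbert) amplitude of the 30–60 Hz
  filtered EOG over the window, one scalar per trial and channel,
  mean-centered in the design. On the study preset, adding these covariates
  moves the eyes−mosaics peak T by well under 5 % (the EOG is independent of
  the effect by construction).

## Known biases and limitations

- **Peak-frequency skew.** The eyes−mosaics log-power difference is
  ln(1 + P_burst(f)/P_noise(f)); with a 1/f noise floor the ratio's maximum
  sits 1–2 Hz above the injected frequency. The recovered peak is therefore
  typically 45–47 Hz for a 44 Hz burst — within the smoothing kernel's
  half-width, and an inherent property of log-power contrasts, not an
  implementation artifact.
- The estimated field FWHM (~115 ms × ~15 Hz on pipeline data) exceeds the
  applied 96 ms × 12 Hz kernel because the wavelet transform itself
  correlates neighboring cells; smoothness estimation correctly reports the
  compound smoothness, and the frequency-dependent wavelet bandwidth is why
  the RPV map (not a global FWHM) drives extent inference.
- Fixed-effects pooling licenses inference about the simulated sample only;
  there is no random-effects group stage (the conjunction analysis plays the
  consistency-checking role instead).
- The ReML component set is intentionally minimal (one variance per stimulus
  type); richer covariance families (per-subject, per-channel) would need a
  different estimator.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own desk-scale defaults: locus-recovery runs use the
full study preset (6 subjects × 183 trials, 20 seeds per presentation);
false-positive-rate runs use 200 effect-free datasets at a reduced layout
(2 subjects, 1 channel, 40 trials per condition pair, no targets), which
leaves the inference machinery identical while keeping the null ensemble
cheap; oracle and smoothness checks use 200–500 simulated fields on the
101 × 57 analysis grid.
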