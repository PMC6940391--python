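# Methods

## The problem this package addresses

In carnivore visual cortex, direction selectivity emerges during a short
window of early visual experience.  Whether that experience *instructs*
the emerging selectivity (the specific spatiotemporal pattern of the
experienced stimulus shapes the specific receptive fields that form) or
merely *permits* maturation of pre-seeded selectivity can be tested by
exposing visually naive animals to gratings animated with scrambled
spatial-phase sequences and asking whether neurons become selective for
those unnatural patterns.  This package implements the computational
machinery of such an experiment: stimulus design, an ideal-observer
response model, single-cell selectivity statistics, population
inference, and a synthetic-data generator that emulates the recordings.

## Stimulus design

One temporal cycle of a drifting sinusoidal grating is discretized into
`n = 8` spatial-phase steps.  Forward motion F is the sequence
`[1 2 3 4 5 6 7 8]`, backward motion B its reverse, and any other
permutation is scrambled motion.  At a 2 Hz cycle rate each step is shown
for `1/(2*8) = 0.0625 s`; a stimulus repeats its cycle 10 times for 5 s.
Because the cycle repeats, sequences that are circular rotations of one
another are the same stimulus; the canonical representative starts with
step 1, which is unique since steps are distinct.  This collapses the
`8! = 40,320` permutations to `8!/8 = 5040` sequences.

Each sequence is scored with three irregularity metrics:

* **Best-aligned correlation with smooth motion.**  Each phase step is a
  spatial sinusoid `sin(2π(x + (step−1)/8))` sampled on the grid
  `x = [0, 1, …, 10]/10`; the correlation of two sequences is the maximum
  over all circular offsets of the summed frame-wise sinusoid products,
  normalized by the geometric mean of the two self-products so that
  self-correlation is 1.  A `mode="as_printed"` variant evaluates the
  literal product kernel `sin(2π((step−1)/8)·x)` (in which step 1 is
  identically zero); it exists purely so the alternative reading of the
  formula can be audited.  The correlation of a sequence against F and
  against B are averaged into `corr_smooth_avg`.
* **Summed total phase interval.**  The sum over consecutive steps
  (including the wrap from last back to first) of the circular step
  distance `min(|Δ|, n−|Δ|)·(2π/n)`.  Smooth sequences attain the
  minimum, 2π.
* **Motion energy.**  One rendered cycle (8 frames × 16 spatial samples
  by default, the smallest grid that resolves all 8 phases without
  aliasing) is Fourier transformed in 2-D and the absolute values of all
  coefficients except the zero-temporal-frequency (static) row are
  summed.  Scrambled sequences spread energy over many spatiotemporal
  frequencies and so carry more motion energy than smooth ones.

### The 10-stimulus family

The experimental family is F, B, six scrambled sequences S1–S6, and two
counterphase gratings CP1/CP2 (standing gratings, mathematically the mean
of the F and B movies; spatial phases default to 0 and π/2, quadrature
covering both null positions).  S6 is fixed to `[8 3 6 2 7 4 1 5]`, a
sequence with essentially zero correlation with smooth motion.  S1–S5 are
not fixed constants; they are chosen by a deterministic, documented rule:
candidates are restricted to `corr_smooth_avg ≤ 0.5`, five evenly spaced
correlation targets between the candidate minimum and that ceiling are
visited from most scrambled upward, and each target takes the nearest
candidate whose best-aligned correlation with every already-chosen
scrambled member (S6 seeded first) is at most 0.6 — so the scrambled
members respond poorly to one another's optimal stimuli while still
spanning low and intermediate similarity to smooth motion.  Ties break by
lexicographic step order, making the family a pure function of its
configuration.  Users can override any of S1–S6 in the family config.

## Ideal kernels and the kernel response matrix

The ideal kernel KX for stimulus X is X's one-cycle X-T movie reversed in
time — the linear receptive field that a neuron perfectly matched to X
would have.  A linear neuron's output is the convolution of its kernel
with the stimulus, so the model response is the peak over circular
temporal lags of the frame-wise product between the time-re-reversed
kernel and the stimulus cycle, normalized by the kernel's response to its
own preferred stimulus (diagonal = 1) and rectified at zero (firing-rate
semantics; a signed mode is kept for diagnostics).  The alignment search
is over temporal circular shifts only: for drifting sequence stimuli a
spatial phase shift is equivalent to a temporal rotation, so a separate
spatial search would be redundant.  The resulting 10×10 matrix (rows =
kernels, columns = stimuli) is deterministic given the family and
sampling.

One symmetry worth noting: KF's response to a stimulus X equals KB's
response to the time-reversed X.  This exchanges the F and B columns and
fixes the (time-symmetric) counterphase columns, but it does **not** map
the KF row onto the KB row at the scrambled columns, because the family
is not closed under sequence reversal.

## Single-cell statistics

With `R` the vector of mean ΔF/F responses to the 10 stimuli:

* **Selectivity index** `SI(n) = R(Sn) / Σ_m R(Sm)`, computed after
  clamping negative mean responses to zero (raw mode available).  SI sums
  to 1; because the family members are mutually correlated, even a
  perfectly kernel-matched cell peaks around 0.2–0.3.
* **Response projection index.**  For referent kernels KXi, KXj with
  ideal response rows normalized to unit vectors u1, u2,
  `D1 = ‖R − (R·u1)u1‖`, `D2 = ‖R − (R·u2)u2‖`, and
  `RPI = (D1 − D2)/(D1 + D2)`.  A response identical to the first
  referent's ideal vector gives −1, to the second +1.  RPI is invariant
  to positive rescaling of R and antisymmetric in the referents.  It
  consumes raw (not blank-subtracted) mean ΔF/F by default — the
  statistic is scale-invariant but not shift-invariant, and the blank
  level in the emulated data is zero-mean.
* **Orientation selectivity** `1 − CirVar = |Σ R(θk) e^{2iθk} / Σ R(θk)|`
  on blank-subtracted per-angle means (doubled angles: orientation
  space).
* **Hotelling gate.**  Each direction-sweep trial is collapsed to the
  complex sum `Σk R_t(θk) e^{2iθk}`; the 2-d (Re, Im) points are tested
  against the origin with a one-sample Hotelling T², using the exact
  `F = (n−p)/(p(n−1)) · T²` transform with p = 2.  Cells pass at
  p < 0.05.
* **Double-Gaussian direction fit.**
  `R(θ) = C + Rp·exp(−angdiff(θ−θp)²/2σ²) + Rn·exp(−angdiff(θ+180−θp)²/2σ²)`
  where `angdiff(x) = min(|x|, |x−360|, |x+360|)` wraps differences onto
  0–180°.  (The absolute values are required for the wrap to work; a
  signed min would be degenerate.)  The fit is bounded least squares with
  an analytic Jacobian: θp initialized at the peak-response angle (and
  its 180° flip), σ started from a deterministic grid {30, 15, 45, 60,
  75}°, C at the minimum response; σ is bounded to [5°, 90°]; the
  lowest-SSE solution wins and the preferred lobe is canonicalized to the
  larger amplitude.  Tuning half-width at half-height is `√(log 4)·σ`.
* **Direction index** `DI = (Rp − max(Rn, 0))/Rp`, at most 1, undefined
  for Rp ≤ 0.

Direction sweeps default to 8 directions × 45°, configurable; the
statistics only require equal spacing covering the full circle.

## Response extraction

`ΔF/F = (F_stim − F_base)/F_base`, with F_stim the mean fluorescence over
the response window ([0, 5] s after onset by default; [0, 7] s for cells
whose responses outlast the stimulus) and F_base the mean over the final
3 s of the preceding interstimulus interval.  Because imaging frames
arrive only every ~1.5 s, a frame belongs to a window when its
acquisition midpoint falls in the half-open interval [t0, t1).  Trials
with non-positive baseline are dropped and logged, never imputed.  Cells
are gated as visually responsive by a classical one-way fixed-effects
ANOVA across all stimulus conditions plus blank on raw ΔF/F (no
transform).

## Population inference

* **Bootstrap difference.**  10,000 replicates; each draws N cells from
  the before population and M from the after population with
  replacement and records the difference of means.  The 5th/95th
  percentiles (linear interpolation between order statistics) are the
  reported bounds; the change is significant-positive when the 5th
  percentile exceeds 0, and symmetrically significant-negative when the
  95th percentile is below 0 (decreases are real outcomes and are
  flagged with their direction).  The interval is the stated 5%/95%
  rule, i.e. nominally a 90% two-sided interval.
* **Covariate correlation** is a Pearson coefficient with its t-based
  p-value (DF = n − 2); **group comparisons** are unpaired two-sample
  t-tests with pooled variance.
* **PCA projection.**  Animal mean-response vectors and the kernel rows
  are each unit-normalized, jointly mean-centered, and projected onto
  the top two principal components (fit jointly by default;
  fit-on-kernels-only available).  Component signs are fixed so the
  largest-magnitude loading is positive, making the plot deterministic.
* **ΔRPI by reference stimulus.**  For each non-trained stimulus X, the
  per-cell RPI(X vs ST) is averaged within each epoch and differenced;
  the trained-vs-trained pair is excluded (identically 0).

## Synthetic data generator

The generator produces the study's input conditions, not a fit to any
particular dataset:

* **Cells.**  A cell's 10-stimulus tuning is `gain · Σk wk·M[k, ·]` for
  mixture weights w over the 10 ideal kernels, with additive Gaussian
  trial noise on ΔF/F (the simplest defensible noise model; a
  multiplicative mode would not change any scale-invariant statistic).
  Defaults: gain 0.3 ΔF/F, noise SD 0.03 (10% of gain), 8 trials per
  stimulus, matching typical GCaMP6s responses and the 8-repetition
  protocol.  Naive-population weights are Dirichlet with concentration
  1.5 on F, B, CP1, CP2 and 0.5 on S1–S6: immature cortex responds like
  typical V1, preferring smooth and counterphase motion.
* **Direction sweeps** are drawn from the double-Gaussian curve with
  `Rn = Rp(1 − DI_true)`, per-cell σ ~ N(30°, 5°) clipped to [15°, 60°],
  and an untuned offset C calibrated by root-finding so the noiseless
  curve attains a per-cell target 1 − CV (per-animal target 0.2 by
  default, jittered SD 0.05 across cells).  Before-population DI is
  N(0.25, 0.1) clipped to [0, 1].
* **Regimes.**  *Instructive*: after-population weights shift linearly
  toward the trained kernel, `w' = (1−e)·w + e·1_ST` with training
  effect e (default 0.5), and the DI generator drops slightly
  (−0.05), emulating selectivity reorganizing toward the trained
  pattern rather than smooth motion.  *Permissive*: weights keep the
  naive distribution and DI rises by 0.25 (the developmentally typical
  increase); RPI is expected unchanged.
* **Fluorescence traces.**  Trial ΔF/F values are rendered as
  `baseline · (1 + r(t) + noise)` where r follows first-order kinetics:
  relaxation toward the programmed ΔF/F with τ_rise (default 0.2 s)
  while the stimulus is on, exponential decay with τ_decay (default
  1 s) afterwards, integrated on a 50 ms grid and sampled at frame
  midpoints every 1.5 s.  Presentations are 5 s on with a ≥ 5 s
  interstimulus interval in a seeded shuffled order.  Slow cells
  (τ_rise ≈ 2.5 s, τ_decay ≈ 5 s) reproduce the situation where the
  extended [0, 7] s response window recovers more of the response than
  the stimulus-locked [0, 5] s window.

What the generator does **not** emulate: biophysical indicator dynamics
(saturation, nonlinearity), neuropil contamination, motion artifacts,
cell-to-cell noise correlations, and realistic skewed response
distributions.  Passing tests therefore demonstrate that the statistics
and inference machinery are correct and calibrated under the assumed
model, not that the pipeline is robust to every pathology of real
two-photon data.

## Numerical choices and problem sizes

* Enumeration is exact (fixing step 1 first yields one representative
  per rotation class); no sampling.
* All generators are pure functions of (spec, seed) via
  `numpy.random.default_rng`; child seeds are drawn below 2³¹.
* Calibration studies in the test suite use: 500 simulated populations
  (n = 50 per group) for bootstrap coverage; 1000 isotropic simulations
  for the Hotelling type-I rate; 100 seeded sweeps across
  DI ∈ {0, 0.25, 0.5, 0.75, 1} for double-Gaussian recovery; and 100
  seeded animals per regime (100 cells per epoch, training effect 0.5)
  for regime recovery — sizes chosen to keep Monte-Carlo error well
  inside the asserted bands while the full suite stays comfortably
  runnable on a laptop.
* In the regime-recovery study the per-cell direction fits use a single
  σ restart (plus the 180° flip): the synthetic sweeps are
  well-conditioned and the argmax initialization is already near the
  optimum, so extra restarts change nothing but runtime.  Analyses of
  messier data should keep the default 5-restart protocol.
* Degenerate inputs (zero response vectors, collinear referents,
  singular trial covariance, non-positive ANOVA variance, non-positive
  fit amplitude) return NaN with a warning rather than raising, so
  population summaries can drop and count them.

## Known limitations

* The exact identities of the paper-family scrambled sequences S1–S5
  are not published; the deterministic selection rule above is this
  package's own choice, so statistics that depend on those columns
  (e.g. RPI values against S1–S5 referents) are reproducible within the
  package but not guaranteed to match the original stimuli.
* Whether the original analysis rectified negative ideal-kernel
  responses or blank-subtracted the responses entering SI/RPI is not
  documented; both choices are exposed as switches, with the defaults
  (rectify; raw means) stated above.
* Real-animal results (per-animal correlations and group means) depend
  on unreleased recordings and are out of scope; the population
  operations are validated on synthetic data only.
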