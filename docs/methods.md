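# Methods

This note documents the models, conventions and numerical choices behind
`freechoice`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and where
design decisions were genuinely open.

## Behavioral preprocessing

**Position tracks** arrive at 5 Hz.  Samples where the animal could not be
identified are linearly interpolated from the nearest valid neighbors (edge
gaps take the nearest valid value); interpolation is applied regardless of
gap length because dropouts are rare in practice (well under 1%), and a
warning is logged above 1%.  Coordinates are then smoothed with a centered
three-sample boxcar; the endpoints use shortened two-sample windows so the
output has the same length and no phase shift.

**ROI assignment.**  The eight-arm maze is modeled as nine disjoint polygons
(eight arms and a central square).  Polygons are closed on their boundary — a
point exactly on an edge belongs to the ROI — and any sample contained in no
polygon (the corridor ring between the center and the arm mouths) is labeled
`center`.  Exact maze dimensions are rig-specific, so geometry is
user-suppliable; the built-in default is an abstract layout in centimeters
(central square of half-width 5, arms 12–45 cm radial, 6 cm wide, at 45°
steps) with 0.01 m per unit.  Containment is evaluated with shapely; the test
suite checks agreement with an independent point-in-polygon implementation on
random points.

**Occupancy, visits, decisions.**  Occupancy is dwell seconds per ROI and by
construction sums to the session duration.  A visit is a maximal run of a
constant arm label; its exit time is the first sample after the run, so visit
durations partition arm occupancy exactly.  An *arm entry* is the first
arm-labeled sample after at least one center-labeled sample (no minimum dwell
is imposed, since none is defined by the paradigm); the wheel-vs-HPF entry
probability is the count of center→wheel entries over center→{wheel or HPF}
entries, with 0.5 the random-choice reference.  Distance traveled attributes
each inter-sample step to the ROI of its origin sample, which makes
"distance outside the wheel arm" an unambiguous partition of the path.

**Bouts.**  Event traces (wheel speed in cm s⁻¹, lick contact as a boolean)
are recorded at 500 Hz and binned to 5 Hz — window mean for speeds, logical
any for contacts.  A bout starts at a supra-threshold bin (≥ 10 cm s⁻¹ for
running; any contact for licking) preceded by at least `min_gap` seconds of
quiet, and ends at the last supra-threshold bin before such a quiet period;
quiet runs shorter than `min_gap` are absorbed.  `min_gap` defaults to 1 s
and is widened to 4 s when aligning photometry so the peri-event signal is
uncontaminated by adjacent bouts.  Conventions fixed here: bout duration is
last-minus-first bin time, so the trailing quiet run is excluded; a
single-bin bout is assigned one bin period (0.2 s) rather than zero, to keep
duration averages meaningful; run amount integrates the *binned* speed over
the bout (rectangle rule), and lick amount counts active 5-Hz bins.  The
dispenser delivers 6 µl per completed group of 10 licks (floor division —
partial groups dispense nothing), so 100 rewards equal 600 µl.

## Photometry

Both channels (465 nm calcium-dependent, 405 nm isosbestic, 20 Hz) bleach
over the session.  Bleaching is modeled as `offset + Σᵢ aᵢ·exp(−kᵢ·t)` with
three exponentials fitted to the full trace by least squares.  The fit uses
variable projection — only the three decay rates are optimized nonlinearly
(log-parametrized, clipped to e⁻³⁰–e⁵ s⁻¹), with the offset and amplitudes
solved linearly at each step — because multi-exponential fitting is
notoriously initialization-sensitive; rate starts are spread over fast
(~0.1 s⁻¹), mid (~0.01 s⁻¹) and slow (~0.001 s⁻¹) regimes and the best of
three starts wins.  If no start converges the fit falls back to a double
exponential with a logged warning.  Each channel is fitted separately.

Normalization is either a z-score of the subtractively corrected trace
(`raw − fit`) over the entire session, or a percentage ΔF/F₀ with F₀ equal to
the fitted bleach curve at each timepoint.  The latter choice of F₀ (rather
than a constant) is the standard photometry convention and removes a purely
multiplicative bleach exactly; it is the default input path for the encoding
model.  The 405-nm channel is processed identically and enters the encoding
model as a regressor (not regression-subtracted), serving as the movement
control.

Peri-event matrices extract `[t−pre, t+post]` windows on the trace grid
around behavioral events; events whose window leaves the trace are dropped
and counted.  ROI-averaged signal maps each 20-Hz sample to the nearest 5-Hz
position sample's label (the rates differ and no finer synchronization is
defined).

## The encoding model

The z-scored 465-nm signal is modeled as

y_ij = β₀ + Σ_k (β_k + b_ki)·x_kij + ε_ij,  b_ki ~ N(0, σ_k²),  ε_ij ~ N(0, σ_ε²),

for sample j of mouse i, with regressors x_k: maze (xy) speed, wheel speed
and lick contact, each convolved with a causal exponential-decay kernel and
z-scored per session, plus the z-scored isosbestic 405-nm trace.  The kernel
is k(τ) = 2^(−τ/1.796 s) on τ ∈ [0, 60 s], sampled at 20 Hz, peak-normalized
to 1; the half-life is the published GCaMP6s fluorescence half-life, so the
convolution imposes the indicator's temporal smearing on the behavioral
inputs.  Peak normalization is a free convention (z-scoring downstream makes
the kernel scale irrelevant to the fit), fixed so kernel-level tests are
well-defined.  Behavioral traces are brought to the 20-Hz response timebase
before convolution (sample-and-hold for the 5-Hz maze speed, window
binning for the 500-Hz traces); the 405 regressor is z-scored but not
convolved, since it is already an optical signal with indicator dynamics.
A behavior that never occurs in a session yields a flat (all-zero) regressor
for that session; the cross-session fit rejects a column that is flat
everywhere.

**Estimation.**  Random slopes are mutually independent (diagonal random-
effects covariance) — with ~10 mice a free correlation structure over four
slopes is not identifiable — and there is no per-mouse random intercept by
default (the model equation has none; a flag adds one).  Fitting is
restricted maximum likelihood.  The residual variance and fixed effects are
profiled out, leaving an optimization over the variance ratios
λ_k = σ_k²/σ_ε² (L-BFGS-B on √λ with a zero lower bound).  Because the
random-effects design is low-rank per mouse, all likelihood quantities reduce
via Woodbury identities to per-mouse cross-product matrices computed once, so
each likelihood evaluation is O(mice · q³) regardless of sample count; a fit
on 120,000 samples takes tens of milliseconds.  A variance ratio estimated at
zero is reported as a converged-but-singular fit with a warning, not a
failure.

**Inference.**  Each fixed effect gets a Satterthwaite degrees-of-freedom
approximation: df = 2v²/(∇v′ A ∇v), where v(θ) is the coefficient variance as
a function of the variance components θ = (σ₁²…σ_q², σ_ε²), ∇v is its
gradient (central finite differences, one-sided at a zero boundary) and A is
the inverse observed REML information (finite-difference Hessian).  In the
degenerate no-random-slope limit this collapses to the classical n − p, and
with dominant random slopes it approaches (mice − 1); both limits are tested,
and estimates, standard errors, df and p-values are cross-checked against
lme4/lmerTest in R and statsmodels MixedLM on the same data.  A non-positive
or non-finite df falls back to the normal approximation with a warning.
Confidence intervals use Satterthwaite-t quantiles.

**Variance explained.**  Nakagawa's decomposition: marginal
R² = var(Xβ̂)/(var(Xβ̂) + Σ_k σ̂_k²·mean(x_k²) + σ̂_ε²), conditional R² adds the
random-slope term to the numerator.  The random-slope contribution
Σ_k σ̂_k²·mean(x_k²) is the natural extension of the intercept-only formula
(for z-scored regressors mean(x_k²) ≈ 1, so it is essentially the sum of
slope variances).

## Figure-level statistics

All tests are implemented from their defining formulas; scipy, pingouin and R
serve only as oracles in tests.  Paired t: t = mean(d)/(sd(d)/√n), df n−1;
all-zero differences return t = 0, p = 1, while a nonzero constant difference
is degenerate.  Wilcoxon signed-rank drops zero differences, ranks |d| with
average ranks for ties, and reports T = min of the signed-rank sums; the
p-value is exact (full enumeration of all 2ⁿ sign assignments via a
dynamic-programming count of rank-sum distributions) for n ≤ 25 without ties,
else a normal approximation with tie and continuity correction.  The 2×2
repeated-measures ANOVA is computed from the full within-subject
sums-of-squares decomposition, each 1-df effect tested against its own
subject-by-effect error; algebraically the interaction F equals the squared
paired t on the per-subject double differences, and this identity is verified
numerically rather than used as the implementation.  The two-sample KS test
uses D = max|ECDF difference| with the plain asymptotic Kolmogorov
distribution at effective size nm/(n+m) for all sample sizes (exact small-n
p-values are out of scope; note scipy's "asymp" mode applies an additional
small-sample adjustment, so the two agree only asymptotically).  Pearson r
uses the Wald t-test with df n−2.  The Fisher r-to-z comparison implements
the independent-samples variant z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) +
1/(n₂−3)); it is not valid for two correlations measured on the same animals.
Bonferroni adjustment is min(1, m·p), with family sizes configured per
analysis plan.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

- **Trajectory**: a semi-Markov alternation of center dwells (exponential,
  mean 3 s) and arm dwells (gamma, shape 2, mean 8 s), arms chosen by a
  preference vector (defaults: wheel 0.28, HPF 0.22, remaining arms sharing
  0.5); transits move between ROI centroids at 20 cm s⁻¹ and within-ROI
  wander is clipped AR(1) jitter.  A configurable fraction of samples
  (default 0.05%) is marked as tracking dropout.
- **Behaviors**: within wheel-arm (HPF-arm) dwells, run (lick) bouts with
  exponential inter-bout intervals and gamma durations; run speed is
  AR(1)-modulated around 25 cm s⁻¹ and floored above the detection threshold,
  licks occur at 7 Hz with 30-ms contacts.  The generator records its drawn
  bout intervals so detector output can be compared against generative truth.
- **Photometry**: the latent signal is produced directly from the encoding
  equation — fixed weights (defaults β₀ = 0, β_xy = 0.25, β_wheel = 0.35,
  β_lick = −0.30, β_405 = 0.10, chosen to mirror the sign structure and
  moderate effect sizes of real recordings), independent per-mouse random
  slopes (sd 0.2), residual sd 1 — using exactly the regressor-construction
  code of the analysis path.  The 405 channel carries a low-pass AR(1) motion
  artifact plus white noise around a positive baseline; its z-scored trace is
  what enters the latent signal, so the artifact reaches the 465 channel only
  through the β₄ path, as in the model.  Both raw channels are the latent (or
  artifact) around a baseline of 100 a.u., multiplied by a triple-exponential
  bleach envelope (amplitudes 0.15/0.15/0.70, rates 0.05/0.005/2·10⁻⁴ s⁻¹ —
  roughly 40% fluorescence loss over 10 min).  The latent is stored for
  parameter-recovery tests.
- **Reproducibility**: each mouse has its own RNG stream at a fixed offset
  from the cohort seed, so sessions are byte-identical under regeneration and
  stable when the cohort is resized.

What the generator does **not** emulate: satiation or fatigue drift over long
sessions, posture/heading, biomechanics of locomotion, hemodynamic or
wavelength-dependent artifact asymmetries, and nonstationary bout statistics.
Passing recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to real-data
violations of them.

## Validation experiments and problem sizes

The standard validation runs (in `freechoice.validation`, exercised by the
test suite and `scripts/acceptance.py`) use these sizes, chosen to make
Monte-Carlo error small relative to the quantities checked while keeping a
full run around a minute:

- Bout segmentation vs a deliberately naive sample-by-sample scanner: 1,000
  random 5-Hz traces with values straddling the threshold; exact agreement
  required.
- Parameter recovery: 50 cohorts of 10 mice × 600 s (12,000 photometry
  samples each), σ_ε = 1, σ_b = 0.2.  The response is the stored generative
  latent; regressors are rebuilt by the analysis path from the raw behavior,
  with the 405 regressor taken through the actual bleach-correction code
  (fitted on a 5× subsampled grid — the envelope is slow — for speed).
  Reported: mean absolute fixed-effect error pooled over the five
  coefficients (with 10 mice the per-slope sampling sd is σ_b/√10 ≈ 0.063
  irrespective of within-mouse sample count, so pooling is what stabilizes
  the summary), 95% CI coverage pooled over all 250 intervals, and the
  fraction of replicates with the correct (+, +, −) xy/wheel/licking sign
  pattern.
- Null calibration: 2,000 replicates per test; n = 12 subjects for paired t
  and the RM-ANOVA interaction, n = 15 for the exact Wilcoxon, and 100 vs 100
  for the asymptotic KS.  The asymptotic KS is expected to sit slightly below
  the nominal 0.05 at these sizes.
- Photometry self-consistency: a noiseless triple-exponential trace must be
  removed to < 10⁻⁶ relative RMS; a single kernel-shaped transient must be
  reproduced exactly by peri-event averaging.

## Known limitations

- The Satterthwaite machinery relies on finite-difference derivatives of the
  REML surface; at an exact zero variance boundary the information matrix is
  one-sided and the df for the affected coefficient falls back to the normal
  approximation.
- The KS p-value is asymptotic only and conservative for small samples.
- When the measured (z-scored) signal rather than the latent is used as the
  response, all coefficients are rescaled by each session's response sd;
  comparisons against generative weights are therefore made on the latent
  scale, and real-data weights should be interpreted in normalized-signal
  units.
- The bleach model assumes the envelope is slow relative to the signal; a
  fast-bleaching session could leak signal variance into the fitted
  exponentials.
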