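# Methods

This note records the modelling choices behind `gaitmos`: what each stage
computes, which parameters matter, what the synthetic generator does and
does not emulate, and the numerical conventions.

## Reference margin of stability

The MoS compares the extrapolated centre of mass (XCoM) with the base of
support (BoS).  The CoM is approximated by the midpoint of the left and
right ASIS markers — a standard reduced-marker surrogate that tracks the
pelvis, not the exact whole-body CoM; absolute MoS values inherit that
approximation.  The XCoM is

    x_xcom = x_com + (v_com + belt) / omega,    omega = sqrt(g / l),

with the belt speed (km/h converted by exactly 1/3.6) added to the
anterior velocity component, and g = 9.81 m/s².

Choices the marker set forces or leaves open:

- **CoM height `l`**: the trial-mean vertical CoM coordinate, giving one
  constant `omega` per trial.  An instantaneous or per-participant `l`
  would be equally defensible; the constant-per-trial reading is the
  conventional one and keeps the pendulum analogy clean.
- **BoS boundary**: the stance foot's forefoot (toe) marker supplies both
  the anterior boundary (its y-coordinate) and — for lack of any other
  lateral landmark in a four-marker set — the mediolateral boundary (its
  x-coordinate).  With lateral foot markers available, the mediolateral
  margin would typically be measured to the lateral malleolus or fifth
  metatarsal instead.
- **Differentiation**: central differences in the interior, one-sided at
  the ends; exact for quadratics, no smoothing by default (a low-pass hook
  can be added upstream of `com_velocity` if a recording needs it).
- **Heel-contact detection**: on a treadmill the stance toe is dragged
  backwards by the belt, so heel contact coincides with a local maximum of
  the toe marker's anterior coordinate.  Peaks are deduplicated with a
  0.3 s refractory period (shorter than any plausible step at the speeds
  of interest, longer than jitter) and checked for strict left/right
  alternation; violations raise with a diagnostic rather than guessing.

Per-step labels are the minima of the anterior (signed) and mediolateral
(absolute, hence ≥ 0) margins over each step — support-foot heel contact
to opposite-foot heel contact — reported in millimetres.

## Principal motion analysis

PMA is a PLS1-family deflation regression on flattened step tensors
(51 time points × 6 channels × 1–2 sensors → 306 or 612 predictors).
Columns of X and y are centred by training means; no variance scaling is
applied, so raw sensor units enter the model and channels with larger
physical ranges carry proportionally more weight — deliberate, as the
method is defined on raw six-axis signals.

The defining equations compute the scores of every component from the
*undeflated* X (`c_l = X w_l`, with `w_l` derived from the deflated
`X_l, y_l`), which differs from conventional NIPALS (`c_l = X_l w_l`) for
l ≥ 2.  Both are implemented:

- `variant="as_printed"` (default): exactly the defining equations, with
  the matching prediction rule `y_hat = x' Σ b_l w_l + y_bar`.
- `variant="nipals"`: conventional PLS1 scores with the standard
  coefficient reconstruction `beta = W (PᵀW)⁻¹ b`; at L = 1 the two
  variants coincide exactly (and match scikit-learn's
  `PLSRegression(scale=False)` to ~1e-14, which the tests use as an
  independent cross-check — the estimator itself never calls it).

Two consequences of the printed convention worth knowing:

- Its training residual does **not** converge to zero at L = rank(X): all
  scores live in a subspace generated from the undeflated X and saturate.
  NIPALS does converge.  Neither behaviour affects the low-L regime the
  method is used in.
- Components beyond the informative ones barely change predictions, so
  the cross-validated RMSE curve is nearly flat past the true latent
  count.  Selecting L by plain argmin (smallest mean CV error, exact ties
  to smaller L — the prescribed rule) therefore occasionally lands in the
  flat tail: on latent-linear data with three true latents and SNR ≈ 10,
  selection falls in 3 ± 1 in roughly three quarters to 85 % of seeded
  replicates, whereas the nipals variant — whose surplus components
  overfit visibly — selects sharply (3 ± 1 essentially always).  We kept
  the argmin rule rather than adopting a one-standard-error or near-tie
  tolerance, since the flat tail is statistically harmless: the selected
  and true-L models differ by < 1e-4 in CV RMSE.

Numerical conventions: double precision throughout; cross-covariance or
score norms below 1e-12 stop extraction early (error only if the first
component is degenerate, so degenerate CV folds downgrade gracefully);
requested L is capped at min(n − 1, d) with a warning.

## Cross-validation protocol

Stratified 10-fold CV: within every (participant, speed) stratum samples
are shuffled by a seeded RNG and dealt round-robin, so per-stratum fold
sizes differ by at most one — each fold sees every participant and speed.
The procedure is repeated five times (repetition r seeds the RNG with
`base_seed + r`); RMSE and Pearson correlation are collected per fold and
summarized as mean ± sd over the k × repetitions fold-level values (the
population of that sd being a choice the protocol leaves open).  Centring
statistics are recomputed inside every training fold; nothing from a test
fold touches the fit.  L is tuned per design matrix by default; a single
shared L across conditions can be imposed by passing a fixed
`n_components`.  The placement grid runs this CV for every single site
and every unordered pair (10 sites → 55 cells per support foot and
direction); left- and right-support steps are never mixed.

The SD-band categorisation (`categorize_mos`) is purely descriptive:
values within one reference sd below the mean are "typical", between one
and two sd below "cautionary", below two sd "high_risk"; only low margins
count as risky.  It is an illustrative statistical framing, not a
clinically validated classifier.

## Synthetic generators

**Latent-linear generator** (`generate_latent_dataset`): X = C Pᵀ + E,
y = C b + e with i.i.d. standard-normal scores, Gaussian loadings and
descending coefficients (n_latent..1).  Defaults: n = 480 samples,
d = 306, three latents, noise_sd_x = 0.1, noise_sd_y = 0.35 (label SNR
≈ 10.7 in amplitude).  This generator matches the estimator's model class
exactly, so it isolates estimation error from model misspecification —
used for parameter-recovery and null-calibration (y replaced by
independent noise) studies.

**Kinematic treadmill generator** (`generate_gait_trial`): a stylized
gait whose MoS truth is available in closed form.

- CoM: constant height (0.95 m), lateral sinusoid at the stride frequency
  (amplitude 0.015 m, phase-locked so the CoM sways toward the support
  foot) plus a slow lateral modulator (0.008 m at 0.11 Hz); anterior
  position a slow sinusoid (0.02 m at 0.07 Hz).  The two slow,
  mutually incommensurate modulators are what makes per-step minima vary
  from step to step — without them every step of a periodic gait would
  carry the same label and regression would be vacuous.
- Feet: heel contacts on a strict grid of one step period (right foot on
  even multiples); cadence rises with belt speed (1.60 / 1.75 / 1.90
  steps/s at 2.5 / 3.0 / 3.5 km/h).  During stance (60 % of the stride)
  the toe is dragged backwards at belt speed from a landing point 0.74 m
  ahead of the pelvis origin; during swing it returns along a smooth
  cosine blend with a sinusoidal-squared lift.  Step width 0.22 m.  These
  geometry defaults were chosen once to land the per-step minima in a
  physiologically plausible range (anterior roughly ±0.1 m across speeds,
  mediolateral ≈ 75–85 mm).
- Warm-up: the first 60 s are generated and their steps discarded, then
  exactly 60 steps per foot are emitted (at speed level defaults).
- Truth: per-step minima are evaluated from the closed-form marker model.
  The velocity entering the truth is the *closed form of the finite
  difference* of the sinusoidal components (central differences satisfy
  the identity Δsin/2dt = cos(ωt)·sin(ω dt)/dt), not a numerical
  derivative of samples — so the reference pipeline, which differentiates
  sampled arrays numerically, reproduces the truth to ~1e-11 mm without
  sharing any code with the generator.  The 1e-6 m consistency bound is
  therefore a genuine two-route check.
- IMU: each site's six channels are a random linear mixture of a few
  periodic latent waveforms — the stride fundamental, the two slow MoS
  modulators, and higher stride harmonics if more latents are requested —
  plus white Gaussian noise (0.05 m/s² accel, 0.02 rad/s gyro) and a
  gravity offset on the accelerometer z channel.  Lower-limb and sacral
  sites load fully on the MoS-coupled latents, the xiphisternum at 0.4,
  and the configured uninformative sites (left wrist, skull vertex) at
  exactly zero — making them pure noise with respect to the labels by
  construction.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: rigid-body limb dynamics and soft-tissue
artifact, impact transients at heel strike, realistic IMU noise spectra
or bias drift, step-time variability (events sit on an exact grid),
marker occlusion, or any nonlinearity between sensor signals and MoS.
Real IMU-to-MoS mappings are only approximately linear; results here
bound the pipeline's behaviour under its own assumptions, not its field
accuracy.

Determinism: every trial derives a private RNG stream from
(seed, participant, speed index), so trials regenerate bit-identically
and can be produced in any order or in parallel.

## Problem sizes used by the tests and acceptance script

Unit tests run on down-scaled trials (12 steps per foot, 5 s warm-up);
the acceptance layer uses full study-scale trials (60 + 60 steps) for the
consistency and placement checks, 20 latent-linear replicates at n = 480
for recovery, 10 seeds each for the null-calibration and
informative-versus-noise rankings, and one repetition of 5–10-fold CV
inside the 55-cell grid.  These sizes keep the whole acceptance run
around fifteen seconds while leaving every check at the scale its
statistics require.

## Known limitations

- The mediolateral BoS boundary from a forefoot marker overestimates the
  lateral margin's repeatability compared to a proper lateral landmark.
- `PMARegressor` is single-response (PLS1); no multi-response, sparse or
  kernel variants, and no inferential statistics on loadings.
- The CV protocol pools participants within folds (as specified); it does
  not estimate leave-one-subject-out generalization.
- The SD-band categories are descriptive only; no fall-outcome validation
  is attempted or implied.
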