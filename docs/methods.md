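# Methods

## The quantities

Over the progression period of stance the ankle moment-angle graph is close
to a triangle-like loop through four corners: (θ_b, 0) at the end of initial
heel plantar-flexion, (θ_c, M_c) at the dorsi→dual transition, (θ_d, M_d) at
the moment peak, and (θ_e, 0) at toe-off. Within each of the three edges on
the rising side and the push-off edge the relationship is nearly linear, so
each phase is summarized by the slope of an ordinary-least-squares fit of
moment on angle (the quasi-stiffness K, N·m/rad), the signed angle change
(excursion Γ, rad), and the fit R². The propulsive work E is the enclosed
loop area; for the idealized four-vertex loop the shoelace rule gives the
closed form

    E = ½ |M_d (Γ_pf − Γ_dl,signed) − M_c (Γ_df + Γ_dl,signed)|.

Angles are radians, dorsiflexion positive; moments are N·m, extensor
(plantar-flexor) positive. Excursions for the dorsi and plantar phases are
magnitudes (their sign never changes in normal gait); the dual-flexion
excursion is kept **signed** because it passes through zero at the singular
speed, and the signed value is what keeps both K_dl = (M_d − M_c)/Γ_dl,signed
and the work expression exactly linear in the regression bases below.

## Generative model (what the synthetic cohort emulates)

No public dataset provides per-trial ankle moment-angle loops with known
ground truth, so the package ships a generator whose defaults emulate a
multi-lab adult cohort:

- **Cohort**: 26 subjects, masses uniform on 46–94 kg, heights uniform on
  1.43–1.87 m. Preferred speed from the Froude relation (below); singular
  speed uniform on (preferred, 1.5 × preferred), reflecting that the
  dual-phase sign change is observed above the preferred speed.
- **Trial schedule** (216 trials): 9 subjects × 4 speeds spanning
  0.75–2.0 m/s, 5 subjects × 20 speeds spanning 1.05–2.6 m/s, and 12
  subjects walking only near (±8%) their preferred speed (80 trials) —
  mirroring the heterogeneity of pooled lab datasets.
- **Transition moments**: M_c = W·H·(0.275 + 0.10·V)·e^η and
  M_d = W·H·(0.48 + 0.16·V + 0.05·V²)·e^η with independent log-normal
  variability η (σ = 0.04). The W·H scaling follows from the lever-arm form
  of the sagittal ankle moment (COP distance scales with foot/toe length and
  hence height; ground-reaction force with body weight), and the speed
  polynomials from the speed dependence of the GRF extrema.
- **Excursions**: Γ_df ~ N(0.20, 0.03) rad, Γ_pf ~ N(0.48, 0.05) rad
  (truncated positive); Γ_dl,signed = 0.10·(V_singular − V)·e^η′,
  σ′ = 0.05, which crosses zero exactly at the singular speed.
- **Sampling**: 131 samples over 0–65% of the gait cycle (0.5% grid), with
  landmarks at 10/30/48/62% (configurable); a heel-strike prefix makes *b* a
  genuine local angle minimum and a short post-toe-off tail makes *e* a
  genuine post-peak minimum. The moment trace gets i.i.d. Gaussian noise
  with per-phase SD (2.9, 8.0, 8.0) N·m.

Calibration: the moment-scale coefficients and the Γ means were solved
analytically so the cohort-level means land near the reference population
values — K_df ≈ 246 N·m/rad, K_pf ≈ 202 N·m/rad, E ≈ 17.6 J. These three
targets are mutually consistent only if the plantar excursion mean is
≈ 0.48 rad (with K_pf·Γ_pf = M_d and the polygon-area identity a 0.35 rad
mean would force E ≈ 7.5 J); 0.48 rad (~27°) is a physiologically reasonable
push-off excursion. The per-phase noise SDs come from R² = S/(S + σ²) with
the default phase signal variances and produce cohort-average phase R² of
≈ 96% (dorsi), ~72% (dual, dragged down by near-singular trials), ≈ 93%
(plantar). A default run reproduces all of these within a few percent.

What the generator deliberately does **not** emulate: curvature within
phases (real loops are only near-linear), intra-trial angle measurement
noise (noise is applied to the moment channel only, so landmark *b* is
recovered exactly on synthetic data), stride-to-stride correlation,
treadmill-vs-overground protocol differences, and any age or gender
structure. Tests passing on this generator therefore certify the pipeline's
numerics and statistical machinery, not its robustness to every artifact of
real motion-capture data.

## Segmentation

*b* is the first local minimum of the angle after 3% of the cycle (detected
on a 5-sample moving average, then refined to the raw argmin — smoothing
alone shifts an asymmetric minimum); *c* is the sample nearest a configurable
percent (default 30%); *d* is the moment maximum, detected on the smoothed
trace and refined to the raw argmax within the smoothing half-window; *e* is
the angle minimum after *d*. Smoothed traces are used for detection only,
never for fitting. At the calibrated noise level *d* is the one genuinely
uncertain landmark (the peak is flat relative to the noise; typical error
~2–3 samples of 0.5% each), which is also why measured dual/plantar
stiffnesses scatter a few percent around truth on noisy trials.

Segments share their boundary samples; a segment with fewer than 3 samples
is an error. A dual segment whose angle spread is below 1e-4 rad is flagged
singular: the stiffness is reported non-finite and the trial is excluded
from the dual-phase model fit (near the singular speed the regression line
is vertical — the joint effectively locks).

## Inverse dynamics

The foot-segment balance is the standard single-segment Newton–Euler form

    M_A = I·α + ω×(I·ω) − (cop − ankle)×F_G − M_G
          − (com − ankle)×(m·g) + (com − ankle)×(m·a_com),

adopted here as the reconstruction of the generic ankle-moment equation
(its published form is available only as a figure, so identity with the
original cannot be asserted symbol-for-symbol — only that this is the unique
standard balance consistent with the described free-body diagram).
Neglecting the ground-reaction moment, foot weight, and the inertial terms
leaves M_A ≈ −(cop − ankle)×F_G; scalar sagittal moments are reported as the
extensor-positive negative Z-component. `assumption_gap` reports the
residual ε_z of that approximation and its size relative to the full moment
(≈ 0 when the assumptions hold; order 10–15% when a realistic foot mass and
loaded-stance accelerations are injected).

## Statistical models

Each response has a derived monomial basis:

- K_df: {1, WH/Γ_df, WHV/Γ_df, WH, WHV}
- K_dl: {1, WH/Γ_dl, WHV/Γ_dl, WHV²/Γ_dl, WH, WHV, WHV², V}
- K_pf: the same eight-term family with Γ_pf
- E: {WH·Γ_x·V^k : x ∈ {df, dl, pf}, k ∈ {0, 1, 2}} (9 terms, no intercept)

with Γ_dl entering signed (see above). Bases are configuration
(`BasisSpec`/`Term`), not hard-coded, so alternates can be tested.

Because the terms are strongly collinear, the informative dimensionality is
established first: PLS regression (scaled) under leave-one-subject-out
cross-validation, selecting the component count that maximizes predicted
R² = 1 − PRESS/SS_tot, with the smallest count kept when the curve is flat
to within 1e-8 (an exactly low-rank response otherwise ties at every count).
The reported model is then a backward-eliminated OLS fit: drop the term with
the largest p-value while it is ≥ α (default 0.05; ties drop the later
column); a numerically exact fit stops elimination since p-values are
undefined at zero residual variance. Rows are weighted equally; row order
never affects any metric.

Diagnostics follow standard regression practice: outliers are rows with
|externally studentized residual| > 3.0 (the threshold is a package choice;
reference analyses report outlier counts but not their rule), and the
headline error is the mean percent error excluding them. A constant
cohort-mean predictor serves as the "average value" baseline a
device-sizing table would otherwise use.

**Stature-based reduction.** People of different statures prefer a common
Froude number Fr = V²/(g·l) with leg length l ≈ 0.53·H; defaults
Fr_opt = 0.25 and 0.53 are literature conventions and configurable.
Substituting V_opt(H) = sqrt(Fr_opt·g·0.53·H) and cohort-mean
preferred-speed excursions into a fitted model collapses every monomial
W^a·H^b·V^c·Γ^d to W^a·H^(b+c/2) — producing models in W and H alone with
half-integer height exponents. The substitution is exact at the operating
point (verified to 1e-9). The dual-flexion reduction is flagged
low-confidence: K_dl is dominated by 1/Γ_dl, and freezing Γ_dl at its mean
discards most of its variance.

Error accounting in the report: general-form and average-value errors are
computed over all usable trials excluding flagged outliers; stature-based
errors over the one trial per subject closest to that subject's
Froude-optimal speed (ties to the slower trial), since those models are
defined only there.

## Numerical choices and edge cases

- Singular-excursion tolerance 1e-4 rad; landmark *b* search starts at 3% of
  the cycle; smoothing window 5 samples.
- A zero angle-variance phase yields a singularity flag, not an exception;
  zero-response rows are skipped (with a log entry) in percent errors.
- The generator resamples the moment-variability draw up to 20 times if it
  produces M_d ≤ M_c and then raises a degenerate-loop error (practically
  unreachable at the defaults).
- Seeds: one integer seed drives cohort, schedule, and every trial via a
  NumPy `SeedSequence` spawn, so datasets, reports, and the acceptance JSON
  are bit-reproducible.
- Problem sizes: the shipped study is 26 subjects / 216 trials; the
  exactness audits use a 26×8 noiseless cohort and 1,000-draw Monte-Carlo
  checks — sizes at which the full pipeline runs in seconds while the
  statistics (support recovery at n = 500 and 1% noise, CV component
  selection at n = 200 with 20 groups) are already stable.

## Known limitations

- The pipeline assumes pre-cropped single-stride stance data; it does not
  detect heel strike or toe-off from force or kinematic data.
- Work is the progression-period loop area; swing-phase work is neglected
  (the ankle is nearly silent there).
- Real printed coefficient tables for the reference population are not
  reproduced — the underlying experimental data are not available — so model
  quality is certified structurally (recovery of known generative
  coefficients, error orderings, calibration bands) rather than by
  coefficient-level comparison.
- Stepwise selection with collinear bases retains a spurious term at roughly
  the α rate; the PLS-CV step is the guard against over-reading the retained
  term list.
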