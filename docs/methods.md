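# Methods

## The foot-placement control model

Steady treadmill walking is laterally stabilized step by step: where the
swing foot lands depends on the body's mediolateral state during the
preceding swing. The package quantifies this with a per-block linear
model,

    FP = β_pos · CoM_pos + β_vel · CoM_vel + ε,

fit by ordinary least squares over the steps of one analysis block. FP is
the mediolateral position of the newly placed heel relative to the stance
heel measured at midstance; CoM_pos and CoM_vel are the mediolateral
position and velocity of the trunk marker (CoM proxy) relative to the
stance heel, sampled at terminal swing. All three are demeaned per block
and per side before left steps are mirrored (mediolateral sign flipped),
so a single regression pools both sides and a wider-than-usual placement
is always positive. Outcomes per block:

* R² — the *degree of foot placement control* (fraction of placement
  variance explained by the CoM state);
* sd(ε) with the n−1 denominator — the *magnitude of foot placement
  error*, in meters.

An intercept is included even though the inputs are demeaned. When
demeaning is exact it estimates to ~0 and changes nothing; when the
demeaning grouping differs from the fit grouping (first/last-30-stride
fits straddle block boundaries) it keeps the residual mean at zero and
preserves the variance decomposition SS_tot = SS_model + SS_res, which the
test suite asserts. The residual sd uses the sample (n−1) convention.
Each step contributes one observation, so a 30-stride block yields up to
60 pooled left+right observations; no outlier rejection is applied beyond
the stride-time gate below.

## Event detection and sampling instants

Heelstrikes are detected kinematically: on a treadmill the heel is most
anterior relative to the trunk at initial contact, so heelstrikes are the
local maxima of `heel_AP − thorax_AP` (per side), with

* zero-phase low-pass smoothing of all marker signals before any
  differentiation or peak search — 2nd-order Butterworth applied
  forward-backward (4th-order effective), cutoff 10 Hz (configurable;
  gait content at 100 Hz sampling lies well below this);
* a minimum same-side spacing of 0.4 s;
* an adaptive prominence gate (a quarter of the 5th–95th percentile range
  of the signal) so numerical ripple on flat segments never fires;
* sub-sample peak refinement by a parabola through the peak and its two
  neighbors;
* removal of events within 0.5 s of the record edges (filter transients);
* alternation repair: of two consecutive same-side candidates the weaker
  (lower peak) is discarded, with a warning counting discards.

Derived instants, per step ending at heelstrike time t_hs:

* **terminal swing** := t_hs (configurable lead in seconds). The
  heelstrike is the only unambiguous instant available from kinematics and
  the CoM state just before contact is the canonical predictor of the
  ensuing placement.
* **midstance** := midpoint of t_hs and the next contralateral
  heelstrike. Alternative definitions can be substituted; this temporal
  definition needs no force data.

**Stride time** is the interval to the next same-side heelstrike; strides
outside [0.4, 3] s are flagged and excluded from fits (counts reported).
**Step width** is |heel_L − heel_R| mediolaterally at midstance. CoM
velocity is a central difference of the smoothed trunk signal (one-sided
at the record edges).

Strides are indexed by the *leading* side — the side of the first detected
heelstrike — rather than always the left; this makes block boundaries, and
hence every numeric outcome, invariant under left/right mirroring of the
recording (asserted in the tests). A stride belongs to a condition window
only if both bounding reference heelstrikes fall inside it, so strides can
never straddle condition or bout boundaries. Conditions are split into
30-stride blocks; trailing incomplete blocks are excluded from per-block
fits but still receive locally demeaned values so that first/last-30
stride fits can use them.

## Local divergence exponent

The local divergence exponent λ quantifies local dynamic stability of the
mediolateral CoM velocity signal (same smoothing and differentiation as
above). Procedure and defaults:

1. **Time normalization**: the signal between the first and last
   reference-leg heelstrike is resampled in a single pass (cubic
   interpolation, uniform grid) to `n_strides × 100` samples, so the
   *average* stride is 100 samples; there is no stride-by-stride warping.
2. **Delay embedding**: 6 dimensions, 25-sample delay.
3. **Neighbor search**: for each embedded point, the 5 nearest Euclidean
   neighbors with temporal separation |i − j| ≥ 50 samples (half an
   average stride, applied symmetrically). Ties are broken toward the
   smaller index so results are exactly reproducible. Reference points and
   neighbors are both restricted to points with a full tracking horizon
   ahead; a pair is tracked for the whole horizon or not used at all, so
   every sample of the divergence curve averages over the same pair set.
   References with too few admissible neighbors are skipped and counted.
4. **Divergence curve**: mean over all pairs of ln‖x_{i+k} − x_{j+k}‖ for
   k = 0 … 999. Distances are floored at 1e-12 before the log so exactly
   periodic inputs stay finite (floor configurable).
5. **λ** := least-squares slope of the curve over its first 50 samples
   (half an average stride), in ln-units per normalized sample;
   `lde_per_stride` multiplies by 100.

The neighbor search is an exact, chunked all-pairs computation (not an
approximate tree), and the tests require bitwise-meaningful agreement
(1e-12) with an independent O(n²) reference implementation, including tie
behavior. Averaging is over pooled pairs (equivalently neighbor-weighted);
a per-reference-first average would weight references with closer
neighbor sets identically here since every reference contributes exactly 5
pairs.

Calibration (reproduced by `scripts/acceptance.py` and the tests): the
r = 4 logistic map yields a slope within a few thousandths of its analytic
Lyapunov exponent ln 2 per iterate; exactly periodic inputs yield |λ| ≤
0.005; cycle-to-cycle jitter strictly increases λ.

In the session pipeline λ is computed once per condition by default, on
the concatenation of the per-bout time-normalized signals (a 30-stride
block provides only 3000 normalized samples against a 1000-sample horizon,
leaving few reference points). A per-block mode
(`RunConfig.lde_scope="block"`, averaging block curves and slopes) is
provided for comparison. Pairs spanning a bout concatenation boundary are
not treated specially; they are a small fraction and the boundary jump
only inflates their initial distance.

## Frontal-plane moment of the vertical GRF

With the CoM as pivot, M = F_grf,vert · (CoP_ml − CoM_ml). Assuming the
CoM midway between the feet, the arm is half the step width: at 750 N and
0.10 m width, M = 37.5 N·m; a 2 mm medial placement error shortens the arm
to 0.048 m (36 N·m), so a corrective moment of F·e = 1.5 N·m must come
from other mechanisms (ankle moments, angular momentum). The module
reproduces exactly these worked numbers and enforces the identity
corrective(f, w, e) ≡ M(f, w/2) − M(f, w/2 − e).

## Synthetic gait generator

The generator emulates the *statistical* structure the analysis assumes —
not gait physics (no pendulum mechanics, no ground reaction forces). Per
step it draws the CoM state and applies the control law exactly, so every
downstream stage has an exact recovery oracle. Defaults (chosen as
order-of-magnitude values typical of steady adult treadmill walking, not
as estimates of any particular population):

| parameter | default | meaning |
| --- | --- | --- |
| `stride_time_mean` | 1.1 s | mean stride duration |
| `stride_time_sd` | 0.02 s | stride-time variability |
| `step_width_mean` | 0.10 m | mean mediolateral heel separation |
| `com_sway_sd` | 0.01 m | CoM position sd at terminal swing |
| `com_vel_sd` | 0.05 m/s | CoM velocity sd at terminal swing |
| `beta_pos` | 1.5 (–) | position gain of the control law |
| `beta_vel` | 0.30 s | velocity gain |
| `sigma_eps` | 0.005 m | placement noise sd |
| `sample_rate` | 100 Hz | marker sampling rate |

CoM states are drawn i.i.d. per step: the control law only constrains the
step-wise linear mapping, and i.i.d. draws make the OLS recovery bounds
analytic (an AR(1) option, `com_dynamics="ar1"`, provides temporally
correlated sway for divergence-sensitivity experiments). Stride times are
built from per-step intervals ~ N(mean/2, sd/√2) truncated at a quarter of
the mean stride, so stride times are marginally N(mean, sd) while both
sides' heelstrike times remain consistent; adjacent stride times share an
interval and are therefore weakly correlated.

Rendering to continuous 100 Hz marker streams: heel AP relative to the
trunk follows one full cosine per cycle with the forward extreme exactly
at each heelstrike — the waveform is locally symmetric around the peak, so
zero-phase smoothing does not bias detected event times. Heel ML is
constant during stance, with a smoothstep transition confined to the last
30% of swing so the swinging heel still marks its previous placement at
the contralateral midstance. Heel height is a half-sine lift during swing.
The trunk ML trajectory is a cubic Hermite spline whose knots are the
terminal-swing instants, with knot values at the drawn CoM positions and
knot *derivatives* at the drawn CoM velocities — a monotone interpolant
cannot prescribe derivatives, and without them the ground-truth CoM
velocity would never be recoverable from the rendered signal. The true
heelstrike times are stored in the output metadata.

What passing the synthetic tests does **not** show about real data: the
generator has no soft-tissue or marker noise by default (a noise-robust
detection test adds 2 mm RMS white noise explicitly), no drift, no
double-support CoP dynamics, no physiologically coupled CoM trajectory
between steps, and its placement noise is Gaussian and i.i.d. Event
detection accuracy and the small-sample behavior of λ on real recordings
must be judged on real data.

## Sizes, tolerances, degenerate inputs

* Test and acceptance runs use 45–300-stride simulations and 2000–5000
  sample calibration series — large enough that OLS recovery bounds
  (validated by a 1000-rep Monte Carlo) and the divergence calibration are
  stable, small enough to iterate quickly.
* The gain-recovery bound ±0.1 and the 15% residual-sd bound are the 99th
  percentile of the Monte-Carlo sampling distribution at 300 strides.
* CSV round-trips are asserted lossless to 1e-9 (floats are written at
  full repr precision).
* Degenerate inputs raise explicit errors: constant markers ("insufficient
  gait"), rank-deficient predictors, zero FP variance, fit windows shorter
  than 10 observations, series too short to embed or track.
* Everything in the analysis chain is deterministic; the only randomness
  anywhere is the generator's seeded `numpy` Generator.

## Known limitations

* The midstance and terminal-swing definitions are kinematic conventions;
  force-plate-defined stance phases may differ by tens of milliseconds,
  which would shift CoM_vel samples slightly.
* Whether demeaning should be per 30-stride block or per condition is a
  genuine modeling choice; per block (and per side) is implemented because
  all outcomes are computed block-wise. Per-condition demeaning would
  slightly raise apparent FP variance.
* The per-condition λ on concatenated bouts includes a handful of
  boundary-crossing pairs (see above).
* C3D reading requires the optional `ezc3d` package and assumes the file's
  axis order already matches the package convention.
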