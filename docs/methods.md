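# Methods

## The estimation problem

An observer watching a ball on a parabolic trajectory has no direct
access to Cartesian state.  The eye measures angles: the retinal size
(angular subtense) θ, the elevation angle γ of the ball above the
eye-level plane, and their time derivatives.  These are ambiguous — a
small near ball and a large far ball produce the same θ; a fast shallow
parabola and a slow steep one can produce similar γ(t) early on.  The
package studies how two internalized constants, gravitational
acceleration *g* and physical ball diameter *s*, calibrate these angles
into an actionable estimate of the remaining time to contact (TTC), and
how robust that estimate is to sensory noise, observer motion and
un-modelled aerodynamics.

## Geometry and dynamics

Coordinates: eye at the origin, x lateral, y vertical up, z depth toward
the launch point; launches and landings at eye level (y = 0).

*Gravity-only flight* is sampled from the closed-form parabola on a
uniform grid (default Δt = 0.01 s) closed with the exact landing time
T = 2·V_y0/g.  Head-on collision courses are constructed with
V_y0 = g·T/2 and horizontal speed Z_init/T aimed at the eye, so the ball
lands exactly at the origin at T.

*Drag flight* integrates dv/dt = −g·ŷ − (ρ·C_d·A/(2m))·|v|·v with
fixed-step classical RK4 at the sampling step.  The eye-level crossing is
localized by bisection on a single RK4 substep from the last airborne
sample; step-halving then changes the flight time by < 1 μs, so the
integrator contributes no measurable error at the default step.  Ball
parameters: baseball r = 0.037 m, C_d = 0.346, m = 0.145 kg; soccer ball
r = 0.11 m, C_d = 0.4, m = 0.43 kg; air density ρ = 1.225 kg/m³.  The
masses and the soccer radius are regulation values supplied as package
defaults (they are configurable; drag curves are mass-sensitive).

*Observer motion* is a straight-line run at constant speed, stationary
until a start delay (default 0.5 s, a typical time before catchers start
moving in the right direction) and timed to reach the interception point
exactly at landing.

## Optical projection

With relative position p = ball − eye and relative velocity v:

* D = |p|, θ = 2·arctan(r/D) (flat-disc subtense of the ball's diameter);
* γ = arctan(p_y / hypot(p_x, p_z)), a spherical elevation above the
  eye-level plane, invariant to head rotation;
* derivatives are analytic: θ̇ = −2rḊ/(D² + r²) with Ḋ = (p·v)/D, and
  γ̇ = (v_y·h − p_y·ḣ)/(h² + p_y²) with h the horizontal range.  Computing
  them from velocities decouples their accuracy from the sampling step;
  finite differencing is kept as a test oracle only.
* V_r = −Ḋ, positive while approaching.

A landing sample that coincides exactly with the eye (perfect head-on
catch, D = 0) is emitted as NaN rather than raising, so whole-flight
pipelines run; every error or precision summary is taken over pre-landing
samples.

Tau is θ/θ̇ where the image expands and NaN elsewhere (while the ball
recedes the ratio is meaningless).  The expansion-discriminability mask
compares the rate of the *radius* subtense (θ̇/2 — the image-edge angular
speed that psychophysical discrimination thresholds are stated for)
against a threshold, 0.004 rad/s by default; with this convention a
baseball spends more than half of every 2 s approach below threshold
while a soccer ball spends strictly less, which is the empirical pattern
the discriminability analysis is meant to capture.

## The calibrated estimator

```
d = s/θ                      (distance from known size)
V_z = s·θ̇/θ²                 (approach speed from known size)
TTC = (2/g)·(s/θ)·γ̇/cos γ    (remaining time to contact)
```

For a head-on eye-level parabola the TTC expression is an identity:
substituting the parabola's kinematics gives exactly T − t, so the only
error on a collision course is the small-angle approximation s/θ ≈ D,
of relative size (r/D)²/3 (≤ 10⁻⁴ beyond a few metres).  The cosine sits
in the denominator; note that γ → π/2 (ball passing directly overhead) is
a genuine degeneracy of the geometry, not of the implementation.

Both priors enter multiplicatively, so a relative error in the size prior
produces the same relative timing error, and a gravity-prior error the
negative of it — the property that makes prior manipulation an
experimental handle.

*Navigation signal.*  An exact predictor decays with slope −1.  The local
slope is estimated by ordinary least squares over a trailing 200 ms
window (20 samples at the default step) with a hold band of ±0.05, both
configurable; the window is a compromise between responsiveness and the
sample noise of a differentiated signal, and the band absorbs slope
estimation error on exact predictions (empirically |slope + 1| < 0.01
there).  Slope above the band ⇒ the prediction decays too slowly ⇒ the
ball lands beyond the observer ⇒ move away from the launch point; below
the band ⇒ move toward it.

*Cue fusion.*  Two TTC cues are combined by inverse-variance weighting
with σ_i = WF_i · estimate_i; the fused variance is (Σσ_i⁻²)⁻¹.  Tau
carries a fixed 10% Weber fraction (the mid-point of its 7–13%
psychophysical range) and is excluded where undefined.  The fused Weber
fraction never exceeds the better cue's when the cues agree, which they
do in use (both estimate the same TTC); with artificially discrepant
inputs the guarantee weakens, which is why the property test constrains
cue disagreement to ±25%.

## Sensory-noise Monte Carlo

Noise on each input x ∈ {θ, γ, γ̇} is additive Gaussian scaled by the
variable's own magnitude, x + N(0, |x|·k), with k = 0.05 for all three by
default.  Draws are i.i.d. across time samples, variables and
simulations — the noise equations carry no temporal correlation term, so
memoryless noise is the literal reading; a θ draw that lands ≤ 0 is
redrawn (physical nonnegativity; probability ≈ 0 at 5% noise).  Output
precision is the timewise Weber fraction WF(t) = SD/mean of the predicted
TTC across simulations (default 10,000 per condition).

Near launch γ ≈ 0, so to first order only θ and γ̇ contribute and
WF ≈ √(k_θ² + k_γ̇²) = 7.07% — the delta-method oracle the Monte Carlo is
tested against.  The "representative" WF is summarized as the median of
WF(t) over the central 80% of the flight pooled across the five launch
distances; the summary window avoids the launch transient and the
landing degeneracy, where the mean TTC crosses zero.

## Population coding experiment

The hypothesis space is 9 contact times (1.8–2.2 s in 0.05 s steps) × 5
gravities (Earth ± 5%, ± 10%) × 5 diameters (baseball ± 2.5%, ± 5%), all
launched head-on from 30 m and probed 0.2 s after launch.  Each optic
variable is encoded by 33 evenly spaced Gaussian tuning curves spanning
the stimulus range the candidates produce (θ: 0.0024–0.0031 rad,
SD 0.00014; γ: 0.045–0.085 rad, SD 0.00325; γ̇: 0.2–0.45 rad/s,
SD 0.01625 — each a 5% Weber width at mid-range), with independent
Poisson spike counts around a peak rate of 50 (detector count and gain
are package choices, exposed as configuration since absolute accuracy
depends on them).  Decoding maximizes the Poisson log likelihood over a
1,000-point grid, ties broken toward the lower stimulus.

A trial exposes one of the nine true trajectories (standard gravity and
size), decodes the three variables, and matches either the prior-free
correlate γ̇/(θ·cos γ) against all 225 candidates or, given priors, the
calibrated remaining-TTC estimate against the nine candidate remaining
times, within a relative margin of ±5% of each candidate's value.  The
reported contact time is drawn uniformly from the matched set (nearest
candidate if empty), a scoring rule that reduces exactly to the 1/9
chance level for an uninformative matched set.  Restricting the
prior-conditioned match to TTC values (rather than a (g, s)-slice of the
bank) is one reading of an under-specified step; it is the variant that
isolates what the priors contribute — collapsing the hypothesis space —
and is the package default.

## Canonical scenarios and problem sizes

* Accuracy/precision family: five 2 s head-on baseball flights from
  15–50 m at Δt = 0.01 s; 10,000 noise draws per condition.
* Off-observer landings: 2 s flights from 50 m to the 3 × 3 grid
  {−5, 0, 5} m × {−5, 0, 5} m around the observer, origin excluded
  (8 endpoints), observer stationary or running from 0.5 s.
* Drag worst case: soccer ball, V_y0 = 9.807 m/s, V_z0 = 25 m/s, drag on;
  observer at the drag landing point, at the midpoint between the vacuum
  and drag landing points, or running from that midpoint (the computed
  run speed, ≈ 8.1 m/s, serves as a cross-check against the published
  value, not as an input).

The default test suite and the acceptance script run these at full size;
everything completes in seconds on one core because the Monte Carlo is
vectorized across simulations and time samples.

## Known limitations

* The estimator is derived for eye-level launches; non-eye-level landings
  and non-spherical balls are out of scope.
* No spin (Magnus force), wind, bounce or altitude-dependent air density
  in the drag model.
* The synthetic optics are noiseless geometric projections; real
  observers foveate, blink and move their heads.  The noise model adds
  magnitude-scaled Gaussian noise per sample but no temporal correlation,
  attention effects or acceleration-detection limits, so passing tests
  certify the computational claims about the model, not human
  performance.
* The population-coding absolute accuracies depend on detector gain and
  count; only orderings (priors > sensory-only > chance; accuracy
  degrading with prior error) are treated as conclusions.
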