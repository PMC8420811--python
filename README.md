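# gsttc — gravity- and size-calibrated time-to-contact for parabolic flight

`gsttc` is a simulation toolkit for a classic problem in visual
psychophysics and computational neuroscience: how can an observer (a
baseball outfielder, say) time the interception of a ball in parabolic
flight when the only information at the eye is a set of ambiguous angular
variables?  The retinal size θ of the ball confounds physical size with
distance; the elevation angle γ and its rate γ̇ confound trajectory shape
with viewing geometry.  The toolkit implements and stress-tests an
estimator that resolves the ambiguity with two pieces of internalized
knowledge — the gravitational acceleration *g* and the ball's physical
diameter *s*:

```
TTC = (2 / g) · (s / θ) · γ̇ / cos γ
```

The ratio *s*/θ recovers metric distance from retinal size; *g*
normalizes the elevation-angle rate into time units.  For a ball on a
gravity-only collision course with the eye the prediction equals the true
remaining time to contact up to the small-angle approximation *s*/θ ≈ D.

What the package lets you do:

* **trajectory** — simulate gravity-only flight (closed form) and flight
  under quadratic air drag (fixed-step RK4), plus observer running paths;
* **optics** — project any (ball, observer) pair into the egocentric
  stream D, θ, γ, γ̇, θ̇, V_r, with analytic derivatives; compute the tau
  cue θ/θ̇ and expansion-discriminability masks;
* **gs_model** — the estimator above, its error and rate-of-change series
  (slope −1 ⇔ exact prediction, deviations form a navigation signal), and
  inverse-variance fusion with tau;
* **noise_mc** — Weber-scaled Gaussian noise on the optical inputs and
  Monte-Carlo output precision as a timewise Weber fraction (SD/mean);
* **popcode** — Gaussian tuning curves with Poisson spiking, maximum-
  likelihood decoding, and the prior-disambiguation experiment over a
  9 × 5 × 5 hypothesis grid of contact times, gravities and sizes;
* **scenarios** — the canonical configurations: five 2 s head-on flights
  (15–50 m), eight off-observer landing points with stationary or running
  observers, and the worst-case soccer-ball drag scenarios.

## Worked example

```python
import numpy as np
from gsttc import WeberConfig, ttc_gs_series, wf_timewise
from gsttc.scenarios import collision_course_family

sc = collision_course_family(distances=(30.0,))[0]   # 2 s head-on flight
traj, _, stream = sc.run()

series = ttc_gs_series(stream, sc.priors, traj.flight_time)
pre = series.times < traj.flight_time
print(f"max |error| = {1000 * np.nanmax(np.abs(series.error[pre])):.3f} ms")

t, wf = wf_timewise(stream, sc.priors, WeberConfig(n_sims=10_000, seed=0))
print(f"median WF   = {100 * np.nanmedian(wf[(t >= 0.2) & (t <= 1.8)]):.2f}%")
```

prints

```
max |error| = 0.141 ms
median WF   = 7.14%
```

The first number says the noiseless estimator tracks the true remaining
time to a fraction of a millisecond over the whole approach; the second
says that with 5% Weber noise on each optical input, the output is still
a ~7% cue — more precise than tau's 10% — so the calibrated prediction is
both accurate and robust.  The `examples/` directory contains one short
script per capability (dynamics, optics, prediction, noise, population
decoding, navigation under drag), and the `gsttc` console command exposes
the same pipelines from a shell (`gsttc --help`).

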