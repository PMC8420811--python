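"""Monte-Carlo precision of the TTC estimator under sensory noise.

Each optical input carries 5% Weber-scaled Gaussian noise.  Running many
noisified predictions gives the output precision as a timewise Weber
fraction (SD/mean of the predicted TTC), alone and fused with the tau cue
(itself a 10% cue, defined only while the image expands).
"""

import numpy as np

from gsttc import WeberConfig, wf_combined
from gsttc.scenarios import collision_course_family

sc = collision_course_family(distances=(30.0,))[0]
traj, _, stream = sc.run()

cfg = WeberConfig(n_sims=10_000, seed=0)
t, wf_gs, wf_tau, wf_c = wf_combined(stream, sc.priors, cfg)

pre = t < traj.flight_time
print(f"max WF of the estimator : {100 * np.nanmax(wf_gs[pre]):.2f}%")
central = (t >= 0.2) & (t <= 1.8)
print(f"median WF (central 80%) : {100 * np.nanmedian(wf_gs[central]):.2f}%")
print(f"max fused WF (with tau) : {100 * np.nanmax(wf_c[pre]):.2f}%")
# Three 5% inputs propagate to about a 7% output (delta method:
# sqrt(0.05^2 + 0.05^2) = 7.07% near launch), always under the 10% Weber
# fraction of tau alone; fusing with tau helps further late in flight.
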