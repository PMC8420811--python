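"""Disambiguating trajectories with gravity and size priors.

225 hypothesis parabolas (9 contact times x 5 gravities x 5 sizes) expose
nearly indistinguishable optics 200 ms after launch.  The optic triplet is
encoded by Gaussian-tuned Poisson detector populations and decoded by
maximum likelihood; a responder then picks the contact time consistent
with the decoded optics within +/-5%.
"""

import numpy as np

from gsttc.gs_model import PriorSpec
from gsttc.popcode import (
    GRAVITY_GRID,
    build_candidate_bank,
    chance_accuracy,
    run_prior_experiment,
)

rng = np.random.default_rng(0)
bank = build_candidate_bank()
trials = 300  # per contact time; increase to 1000 for tighter estimates

print(f"chance level              : {100 * chance_accuracy():.1f}%")
acc = run_prior_experiment(trials, None, 0.05, rng, bank)
print(f"sensory information only  : {100 * acc:.1f}%")
acc = run_prior_experiment(trials, PriorSpec(), 0.05, rng, bank)
print(f"correct gravity+size prior: {100 * acc:.1f}%")
acc = run_prior_experiment(trials, PriorSpec(gravity=GRAVITY_GRID[0]), 0.05, rng, bank)
print(f"gravity prior off by -10% : {100 * acc:.1f}%")
# Without priors the decoded correlate matches many (TTC, g, s) candidates,
# so performance barely beats 1/9.  Calibrating the same decoded optics with
# correct priors collapses the hypothesis space and triples the accuracy;
# a biased gravity prior gives most of that benefit back.
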