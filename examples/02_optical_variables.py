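"""Project a head-on flight into the angles an observer actually sees.

A baseball launched 30 m away on a 2 s collision course is reduced to the
egocentric variables available at the eye: retinal size, elevation angle,
their rates, and the fraction of the flight during which the image
expansion is too slow to discriminate.
"""

from gsttc import BASEBALL, EARTH, expansion_discriminable, make_head_on, project, simulate_vacuum

traj = simulate_vacuum(make_head_on(30.0, 2.0, EARTH), EARTH)
stream = project(traj, ball=BASEBALL)

for i in (0, 50, 100, 150):
    print(
        f"t={stream.times[i]:.1f} s  D={stream.distance[i]:5.2f} m  "
        f"theta={stream.theta[i]*1e3:.3f} mrad  gamma={stream.gamma[i]:.3f} rad  "
        f"gamma_dot={stream.gamma_dot[i]:.3f} rad/s"
    )

_, frac = expansion_discriminable(stream)
print(f"\nfraction of flight with expansion below the 0.004 rad/s threshold: {frac:.2f}")
# For a distant baseball the image grows too slowly for most of the flight,
# so expansion-based cues (like tau) are unusable early; the elevation angle
# and its rate remain well above discrimination thresholds throughout.
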