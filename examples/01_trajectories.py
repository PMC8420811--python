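"""Simulate a ball flight with and without air drag.

Launches a soccer ball at 9.807 m/s vertical and 25 m/s horizontal speed
and compares the ideal gravity-only parabola with the drag trajectory.
"""

from gsttc import EnvSpec, LaunchState, SOCCER, simulate_drag, simulate_vacuum

launch = LaunchState(position=(0, 0, 0), velocity=(0, 9.807, 25.0))

vacuum = simulate_vacuum(launch, EnvSpec())
drag = simulate_drag(launch, SOCCER, EnvSpec(drag_enabled=True))

print(f"gravity only : flight {vacuum.flight_time:.3f} s, range {vacuum.landing_point[2]:.2f} m")
print(f"with air drag: flight {drag.flight_time:.3f} s, range {drag.landing_point[2]:.2f} m")
print(
    f"drag shortens the flight by {vacuum.flight_time - drag.flight_time:.3f} s "
    f"and the range by {vacuum.landing_point[2] - drag.landing_point[2]:.2f} m"
)
# The quadratic drag force removes kinetic energy throughout the flight, so
# a real ball lands earlier and closer than the ideal parabola predicts.
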