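"""Velocity map of a learning rule on the rotation manifold.

For a 2x2 rotation mixing matrix the weight matrix can be parameterized as
W = (W11, W12; -W12, W11).  The expected weight change at each grid point,
computed by quadrature over the source density, reveals the rule's fixed
points; for the error-gated rule all four ICA solutions are stable sinks
while for the Cichocki rule two of them are unstable.
"""

import numpy as np

from eghr import Prior, make_mixing, velocity_map

prior = Prior(family="laplace", gamma=100.0)
mixing = make_mixing("rotation", theta=np.pi / 6)

for rule in ("eghr", "cichocki"):
    # the full reference grid; expect a couple of minutes per map
    vm = velocity_map(rule, prior, mixing)
    print(f"\n{rule}: {len(vm.fixed_points)} fixed points")
    for loc, classification in vm.fixed_points:
        ang = np.degrees(np.arctan2(loc[1], loc[0])) % 360
        print(f"  (W11, W12) = ({loc[0]:+.3f}, {loc[1]:+.3f})"
              f"  angle {ang:6.1f} deg  {classification}")
# The ICA solutions sit at angles 30, 120, 210, 300 degrees on the unit
# circle; 'stable' marks attracting solutions, 'unstable' repelling ones.
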