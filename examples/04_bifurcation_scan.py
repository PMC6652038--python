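"""A coarse bifurcation scan of the saturation scenario across its Hopf point.

One integration per delay; after discarding the transient, the extrema of
v(t) and an attractor label are recorded.  The onset of oscillation in the
scan should bracket the analytically computed critical delay.
"""

import numpy as np

import virhopf as vh

scenario = vh.get_scenario("case2a")
summary = vh.hopf_summary(scenario.params)
print(f"analytic critical delay tau* = {summary.tau_star:.4f}")

grid = np.arange(2.0, 9.0, 1.0)
diagram = vh.scan_tau(scenario.params, grid, t_end=2500.0, transient=2000.0, step=0.02)
for pt in diagram.points:
    if pt.maxima.size:
        extent = f"v extrema in [{pt.minima.min():9.3f}, {pt.maxima.max():9.3f}]"
    else:
        extent = f"settled at v = {pt.final_state[2]:9.3f}"
    print(f"tau = {pt.tau:4.1f}: {pt.classification:12s} {extent}")
print(f"scan onset of oscillation: tau = {diagram.onset_of_oscillation():.1f}")

# Rows below tau* settle onto E* (label 'equilibrium'); above it the window
# still contains the growing spiral toward the limit cycle, so maxima drift
# and the label is 'aperiodic' until the cycle settles at longer horizons.
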