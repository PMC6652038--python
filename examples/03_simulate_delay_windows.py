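"""Integrate the bilinear scenario inside and outside a stability window.

The delay system is integrated by fixed-step RK4 with the lag served from
the stored solution history.  Starting from a 5% perturbation of E*, the
virus load settles back at tau=15 (inside the restabilization window) but
locks onto a sustained oscillation at tau=20.
"""

import virhopf as vh

base = vh.get_scenario("case1b").params
eq = vh.find_positive_equilibrium(base)
print(f"positive equilibrium: v* = {eq.v:.4f}")

for tau in (15.0, 20.0):
    traj = vh.integrate(base.with_tau(tau), t_end=2000.0, step=0.01)
    tail = traj.v[traj.times > 1800.0]
    amplitude = tail.max() - tail.min()
    sustained = vh.oscillation_sustained(traj)
    print(f"tau = {tau:4.1f}: v-amplitude over [1800, 2000] = {amplitude:10.4f}  "
          f"sustained oscillation: {sustained}")

# The amplitude at tau=15 is orders of magnitude below v(t)'s scale (the
# trajectory has collapsed onto E*), while tau=20 keeps a finite-amplitude
# limit cycle — a delay-induced stability switch.
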