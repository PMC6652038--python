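"""Basic reproduction number and equilibria for two built-in scenarios.

R0 splits into a virus-to-cell part k*f1(u0,0)/(d2*d3) and a cell-to-cell
part f2(u0,0)/d2; whenever R0 > 1 a unique positive equilibrium E* exists
alongside the infection-free state E0 = (s/d1, 0, 0, 0).
"""

import virhopf as vh

for name in ("case1a", "case2a"):
    params = vh.get_scenario(name).params
    r0 = vh.basic_reproduction_number(params)
    e0 = vh.infection_free_equilibrium(params)
    star = vh.find_positive_equilibrium(params)
    print(f"--- {name} ({params.f1.family} incidence) ---")
    print(f"R0 = {r0.r0:.4f}  (virus-to-cell {r0.virus_to_cell:.4f}, "
          f"cell-to-cell {r0.cell_to_cell:.4f})")
    print(f"E0 = (u0, 0, 0, 0) with u0 = {e0.u:.1f}")
    if star is not None:
        print(f"E* = (u*={star.u:.4f}, w*={star.w:.4f}, v*={star.v:.4f}, "
              f"z*={star.z:.4f}), max residual {star.max_residual:.2e}")
    print()

# R0 > 1 in both scenarios, so the infection can establish itself and the
# printed E* is the endemic steady state whose stability the delay controls.
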