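"""Steady-state renewal: a bounded, continuously replaced structure.

Runs the spatial model with generation-scheduled whole maturation
(n_wm = n_wm0 - g) and a finite lifespan — the configuration that
simulates colonic-crypt renewal: a dividing region persists around the
clonogenic cell while terminally differentiated cells stream outward
and die at the edge, keeping the population constant.
"""

import math

from cryptsim import (
    CellState,
    RuleParameters,
    classify_age,
    project_cylinder,
    run_steady_state,
)

params = RuleParameters(c=6, n_wm0=11, L=35, steady_state=True, T=210)
run = run_steady_state(params)

totals = [s.n_cells for s in run.snapshots]
print(f"Population: {totals[:8]} ... settles at {totals[-1]} cells")
print(f"Constant from step {next(t for t in range(211) if totals[t:] == [totals[-1]] * (211 - t))} on:"
      f" production (divisions) balances loss (death at age L={int(params.L)}).")

t = 210
rec = run.record
state_radii: dict[str, list[float]] = {}
for lab, (x, y) in run.snapshot_at(t).positions.items():
    s = (CellState.CLONOGENIC if lab == 0
         else classify_age(t - rec.birth_time[lab], rec.generation[lab], params))
    state_radii.setdefault(s.name, []).append(math.hypot(x, y))
for name in ("CLONOGENIC", "I", "M", "W"):
    radii = state_radii.get(name, [])
    if radii:
        print(f"  {name:<10} {len(radii):>5} cells, radius {min(radii):5.1f} .. {max(radii):5.1f}")
print("Mature dividing cells stay near the centre; wholly mature (W) cells")
print("occupy the periphery — the planar picture of a crypt's proliferative")
print("base and differentiated upper wall.")

proj = project_cylinder(run, circumference=42, t=27)
heights = [h for _, h in proj.values()]
print(f"\nCylinder projection at t=27 (42-cell circumference): {len(proj)} cells, "
      f"height span {min(heights):.1f} .. {max(heights):.1f} — the 3D crypt-like view.")
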