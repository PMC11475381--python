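"""Pulsatile flow through a coronary bifurcation with Windkessel beds.

A parent vessel splits into two unequal daughters; terminal resistances
follow the Murray power law (flow ~ radius^2.27) and each bed couples to a
scaled ventricular pressure, reproducing the systolic throttling of
coronary flow.  Prints the Murray flow split, junction mass balance and
cycle-mean pressures.
"""

import numpy as np

import autoffr as af

blood, wall = af.BloodProperties(), af.WallLaw()
mesh = af.make_bifurcation_mesh1d(r_parent=0.2, r_daughters=(0.12, 0.16),
                                  lengths=(2.0, 2.0, 2.5), spacing=0.02)
rcor = af.total_resistance(af.PerfusionTargets(), "left")
beds = af.distribute_terminals(mesh, rcor, blood, wall, plv=af.scaled_plv("left"))
for b in beds:
    print(f"terminal vessel {b.vessel_id}: flow fraction {b.flow_fraction:.3f}, "
          f"RTf = {b.RTf:.3e} dyn s/cm^5")

solver = af.CoronarySolver(mesh, af.InflowWaveform.default("left"), beds, blood, wall,
                           af.SolverConfig(dt=2e-3, n_cycles=4))
sol = solver.solve()

print(f"cycle-to-cycle inlet pressure change: {sol.periodicity:.2%}")
print(f"max junction mass defect: {sol.junction_mass_error():.2e} (relative)")
for vid in (0, 1, 2):
    res = af.compute_cffr(sol, vid, 99.0)  # distal end of each vessel
    print(f"vessel {vid}: mean distal P = {res.Pd_mean_mmhg:.1f} mmHg, cFFR = {res.cffr:.3f}")

# The flow fractions follow r^2.27 (the larger daughter takes ~2x the flow of
# the smaller); mass is conserved at the junction to solver precision and the
# unobstructed tree keeps cFFR close to 1 everywhere.
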