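"""Plaque formation over a lifetime under three clearance scenarios.

Simulates the full aggregation model for 100 years per cell and compares
the percentage of cells associated with plaques (aggregate > 30 monomer
units) by age 100, plus the shape of the prevalence curve, for:
efficient clearance, clearance impaired from birth, and clearance that
declines with age as the neprilysin pool decays.
"""

from plaquesim import build_model2, curve_shape, prevalence_curve, simulate_ensemble

N_CELLS = 60  # increase for tighter confidence bands

for variant in ("normal", "constant_impaired", "declining"):
    ens = simulate_ensemble(build_model2(variant), n_cells=N_CELLS, base_seed=2)
    curve = prevalence_curve(ens)
    shape = curve_shape(curve)
    p50, p100 = curve.at_age(50), curve.at_age(100)
    print(f"{variant:18s} prevalence 50y: {p50:5.1f}%   "
          f"100y: {p100:5.1f}% +/- {curve.ci_at_age(100):.1f}   "
          f"curve shape: {shape.label}")

print()
print("Reading: efficient clearance keeps plaque-bearing cells rare;")
print("lifelong impairment produces plaques at all ages (roughly linear")
print("rise); age-declining clearance concentrates plaque formation after")
print("age 60 (convex, accelerating rise), which is the realistic pattern")
print("for sporadic late-onset disease.")
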