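"""Monomer turnover in single cells: why clearance rate matters.

Simulates the turnover-only model (production + first-order clearance) at
the normal and the AD-measured clearance rates, and reproduces the
mean-versus-threshold-exceedance correlation analysis across 100 cells.
"""

from plaquesim import (
    build_model1,
    correlate_mean_vs_exceedance,
    simulate_ensemble,
)

for label, k_deg in [("normal", 2.1e-5), ("AD", 1.5e-5)]:
    ens = simulate_ensemble(build_model1(k_deg), n_cells=100, base_seed=1)
    grand_mean = ens.stack("Abeta").mean()
    print(f"{label} clearance (k_deg={k_deg:g}/s):")
    print(f"  grand mean Abeta = {grand_mean:.3f} "
          f"(stationary prediction {1.86e-5 / k_deg:.3f})")
    for thr in (1, 4):
        res = correlate_mean_vs_exceedance(ens, threshold=thr)
        print(f"  threshold {thr}: Pearson r = {res.pearson_r:.2f}, "
              f"slope p = {res.slope_p_value:.2g}")

print()
print("Reading: per-cell mean Abeta and the fraction of time the count")
print("exceeds a low threshold are strongly correlated (r ~ 0.85) at")
print("threshold 1; at threshold 4 the excursions are too rare for the")
print("mean to predict them well.")
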