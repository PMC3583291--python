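"""Single-parameter scan: how the dimerisation rate shapes plaque burden.

Scans k_dimer over two decades around its default under normal clearance
and reports prevalence at age 100 with 95% confidence half-widths, median
lag time, and mean final plaque size per value.
"""

from plaquesim import build_model2, scan_parameter

result = scan_parameter(
    build_model2("normal"),
    name="k_dimer",
    values=[1.2e-8, 6e-8, 1.2e-7, 6e-7, 1.2e-6],
    n_cells=40,  # small demo ensemble
    base_seed=4,
)

print(result.to_dataframe().to_string(index=False))
print()
print("Reading: prevalence rises steeply (sigmoidally in log-k_dimer) with")
print("the dimerisation rate and the lag time shortens, while final plaque")
print("size barely moves — dimerisation controls whether and when a plaque")
print("is seeded, not how big it grows.")
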