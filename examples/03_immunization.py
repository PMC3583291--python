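"""In-silico passive immunization against amyloid dimers.

Adds an antibody bolus (1000 molecules plus continued supply) at different
ages to cells with age-declining clearance, and compares the plaque burden
at age 100 against untreated controls simulated with the same random
numbers.
"""

from plaquesim import age_response_experiment, build_model2

result = age_response_experiment(
    build_model2("declining"),
    kind="anti_dimer",
    ages_years=(1, 50, 60, 70, 80),
    n_cells=40,  # small demo ensemble; increase for smoother numbers
    base_seed=3,
)

print("percentage of cells associated with plaques at age 100:")
prev = result.prevalence_at(100)
print(f"  untreated control    : {prev['control']:5.1f}%")
for age in (1, 50, 60, 70, 80):
    print(f"  antibodies at age {age:2g} : {prev[age]:5.1f}%")

print()
print("Reading: the earlier the anti-dimer antibody is delivered, the")
print("smaller the eventual plaque burden; administration in infancy")
print("essentially abolishes plaque formation, while late administration")
print("still helps but cannot undo established plaques.")
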