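# plaquesim

Exact stochastic simulation of amyloid-beta (Aβ42) turnover, dimerisation
and plaque formation near single brain cells over a simulated human
lifetime — with in-silico passive-immunization experiments, parameter-scan
machinery, SBML model exchange and the trajectory statistics needed to
analyse the results.

## Who this is for

Systems-biology and neurodegeneration researchers who want to ask
population-scale questions about amyloid aggregation ("what fraction of
cells carries a plaque by age 100 if clearance declines with age?", "how
much does an anti-dimer antibody delivered at 50 help?") with a model small
enough to reason about.  Local Aβ copy numbers are tiny — the stationary
mean free-monomer count is below one molecule per cell neighbourhood — so
aggregation is a rare stochastic event and must be simulated exactly, not
averaged.

## The model

Molecule counts evolve as a continuous-time Markov jump process sampled
with the Gillespie direct method (SSA).  The core aggregation model has
species `Abeta` (free monomer), `AbDim` (dimer), `AbP` (aggregate size in
monomer units) and `Nep` (neprilysin, the Aβ-degrading enzyme), with
hazards

```
production        ∅ → Abeta                 k_prod
clearance         Abeta → ∅                 k_deg·Abeta   (or k_deg·Abeta·Nep/Nep0)
dimerisation      2 Abeta → AbDim           k_dimer·Abeta·(Abeta−1)/2
dedimerisation    AbDim → 2 Abeta           k_dedimer·AbDim
nucleation        2 AbDim → AbP(+4)         k_pf·AbDim·(AbDim−1)/2
growth            Abeta + AbP → AbP(+1)     k_pg·Abeta·AbP²/(k_pghalf²+AbP²)
disaggregation    AbP(−1) → Abeta           k_disagg·AbP
enzyme decay      Nep → ∅                   k_degNep·Nep
```

A cell is "associated with plaques" once `AbP > 30` monomer units at any
recorded time.  Three clearance scenarios are built in: `normal`
(k_deg = 2.1e-5 /s), `constant_impaired` (1.5e-5 /s from birth), and
`declining` (clearance tracks the decaying neprilysin pool, falling from
the normal to the impaired rate around age 60).  A dimer-mediated growth
variant (Model 3) and a turnover-only model (Model 1) complete the set.
Interventions — anti-dimer antibody, anti-monomer antibody, production
inhibition — are timed events added to the model.  See
[docs/methods.md](docs/methods.md) for assumptions, parameter values,
units and design choices.

## Worked example

```python
from plaquesim import (build_model2, simulate_ensemble, prevalence_curve,
                       age_response_experiment)

# 100 cells, 100 years each, age-declining clearance
ens = simulate_ensemble(build_model2("declining"), n_cells=100, base_seed=1)
curve = prevalence_curve(ens)
print(f"plaques by 50y: {curve.at_age(50):.0f}%  by 100y: "
      f"{curve.at_age(100):.0f}% +/- {curve.ci_at_age(100):.0f}")
```

prints

```
plaques by 50y: 15%  by 100y: 37% +/- 9
```

i.e. under declining clearance the plaque burden accelerates late in life,
reaching ~37% of cells (95% band ±9 points at 100 cells) by age 100, while the
same experiment with `build_model2("normal")` stays below ~10% — the
calibrated contrast between normal and at-risk ageing.  The
[examples/](examples) directory contains one short script per capability
(turnover statistics, ageing scenarios, immunization, parameter scans,
SBML round-trip); each prints its numbers with a line on how to read them.

A thin CLI wraps the same calls:

```bash
plaquesim simulate --model model2 --variant declining --cells 100 --seed 1
plaquesim intervene --kind anti_dimer --ages 1,50,60,70,80 --cells 100 --seed 1
plaquesim export-sbml --model model2 --variant declining --out model.xml
```

Every run writes manifests with per-cell seeds and a content hash of the
resolved model, and identical invocations reproduce byte-identical output.

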