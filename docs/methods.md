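# Methods

## The modelled system

`plaquesim` simulates the fate of amyloid-beta (Aβ42) molecules in the
neighbourhood of a single brain cell over a human lifetime, as a
continuous-time Markov jump process on integer molecule counts.  Local Aβ
copy numbers are very small (the stationary mean free-monomer count is below
one molecule), so the dynamics are dominated by chance: whether a particular
cell ever seeds an aggregate is a rare-event problem, and deterministic
rate equations are uninformative.  Every simulation run represents one cell;
population-level quantities (the percentage of cells associated with
plaques at a given age) are read off ensembles of independent runs.

Three nested models are provided.

**Model 1 — monomer turnover.**  Production at a constant rate
`k_prod = 1.86e-5 molecules/s` and first-order clearance at `k_deg`
(`2.1e-5 /s` for efficient clearance, `1.5e-5 /s` for the impaired rate
measured in Alzheimer's patients).  This is an immigration–death process
whose stationary law is Poisson(`k_prod/k_deg`); the package uses that
closed form as a test oracle.

**Model 2 — turnover plus aggregation** (the central model).  Eight
reactions over species `Abeta` (free monomer), `AbDim` (dimer), `AbP`
(aggregate size, counted in monomer units), `Nep` (neprilysin, initial
1000):

| reaction | state change | hazard |
|---|---|---|
| production | `Abeta + 1` | `k_prod` |
| clearance | `Abeta - 1` | `k_deg·Abeta` (constant variants) or `k_deg·Abeta·Nep/Nep0` (declining) |
| dimerisation | `Abeta - 2, AbDim + 1` | `k_dimer·Abeta·(Abeta-1)/2` |
| dedimerisation | `AbDim - 1, Abeta + 2` | `k_dedimer·AbDim` |
| nucleation | `AbDim - 2, AbP + 4` | `k_pf·AbDim·(AbDim-1)/2` |
| growth | `Abeta - 1, AbP + 1` | `k_pg·Abeta·AbP²/(k_pghalf² + AbP²)` |
| disaggregation | `AbP - 1, Abeta + 1` | `k_disagg·AbP` |
| enzyme decay | `Nep - 1` | `k_degNep·Nep` |

Growth saturates in aggregate size (Hill exponent 2) so plaques stop
growing near the size where disaggregation balances saturated growth
(`AbP* ≈ k_pg·E[Abeta]/k_disagg`, on the order of 10² monomer units at the
default rates); growth also vanishes at `AbP = 0`, so an aggregate
that fully dissolves is gone until a fresh nucleation.  A cell is "associated
with plaques" once `AbP` strictly exceeds 30 monomer units at any recorded
time — aggregates above that size essentially never dissolve completely —
and its lag time is the first recorded age at which that happens.
Association is cumulative; the non-cumulative variant (`point_prevalence`)
is also provided because interventions can shrink existing plaques back
below threshold.

**Model 3 — dimer-mediated growth.**  As Model 2 but aggregates grow by
dimer addition (`+2` units per firing, hazard `k_pg·AbDim·Hill(AbP)`) and
disaggregation releases dimers (`-2` units).  Aggregate size then stays
even, so the two-unit disaggregation step cannot underflow.  No independent
parameter calibration exists for this variant; it reuses the Model 2
defaults and every value can be overridden.  Its outputs are known to be
hyper-sensitive to parameters and are not acceptance-tested quantitatively.

### Clearance variants

* `normal` — constant `k_deg = 2.1e-5 /s`, `k_degNep = 0`.
* `constant_impaired` — constant `k_deg = 1.5e-5 /s` from birth.
* `declining` — clearance proportional to the neprilysin pool, normalised
  to its initial count: hazard `k_deg·Abeta·Nep/Nep0` with `Nep0 = 1000`
  and `k_degNep = 1.8e-10 /s`.  The enzyme pool then decays to ~711 copies
  by age 60 (closed form `1000·e^(-k·t)`), i.e. ~30% loss, and the
  effective per-monomer clearance falls from the normal rate to the
  AD-measured rate (~1.5e-5 /s) around age 60.  The normalisation by `Nep0`
  is deliberate: an unnormalised `k_deg·Abeta·Nep` hazard would make
  clearance a thousand-fold too fast at birth and is inconsistent with both
  the units of `k_deg` and the intended behaviour that the declining model
  *starts* at the normal rate.

### Aggregate bookkeeping

`AbP` counts monomer units held in aggregates (the plaque threshold, the
half-saturation constant `k_pghalf = 4 molecules` and the growth/disaggregation
steps are all expressed in monomers).  Nucleation therefore converts two
dimers into an aggregate of size 4.  This mass-conserving convention is a
deliberate design choice: treating the nascent aggregate as a single unit
instead starves it below the half-saturation size and measurably
under-produces plaques, missing the model's calibration conditions (the
declining-clearance prevalence floor and the plaque-formation-rate scan
plateau that the acceptance suite checks).  With the size-4 convention the
calibration conditions are met with no parameter changes.  A size-4 seed
also starts exactly at the half-saturation size, which is why `k_pghalf = 4`
is a natural calibrated value.

## Simulation algorithm

The engine is the exact Gillespie direct method: waiting times are
exponential in the total hazard, the firing channel is chosen
proportionally to its hazard, and the state advances by the reaction's
stoichiometry.  Time-triggered events (used for interventions) are applied
atomically when simulated time crosses the trigger; the pending waiting
time is discarded and resampled afterwards, which is exact because the
exponential distribution is memoryless.  Events scheduled beyond the
simulation horizon are ignored with a warning.

State is recorded on a fixed grid (default 500 points over 100 years, i.e.
0.2-year resolution) as a right-continuous step function: the value at grid
time `t` is the state after the last firing at or before `t`.  Cumulative
per-reaction firing counters are recorded on the same grid; they are the
instrument used to measure, e.g., how often the neprilysin-dependent
clearance reaction runs.  Lag times consequently have 0.2-year resolution,
not exact-event resolution.

Correctness of the sampler is established two ways: the empirical state
distribution on a small two-species network matches the matrix-exponential
solution of the chemical master equation (total-variation distance < 0.05
at 10,000 replicates), and the Model 1 occupancy statistics match the
Poisson stationary law within Monte-Carlo error.

The inner loop is compiled with numba.  A plaque-bearing cell-century is
~3×10⁷ firings (the growth/disaggregation churn at the plaque's steady
size dominates) and simulates in roughly a second; plaque-free cells are
hundreds of times cheaper.  An exact linear fast-forward
(`fast_forward_linear`) is provided for plaque-free epochs — it advances an
immigration–death subnetwork by its closed-form transition law (binomial
survival + Poisson influx) — but it is disabled by default and refuses to
run while any nonlinear hazard is active.

### Seeding and reproducibility

One root seed per ensemble; per-cell seeds are derived through
`numpy.random.SeedSequence`, so results are independent of execution order
and bit-for-bit reproducible from `(model, seed)`.  Scan experiments derive
each value's seed from `(root seed, parameter name, value)`, never from the
position in the value list, so scans are invariant to scan order and to
subsetting.  Ensemble manifests record every per-cell seed plus a content
hash of the resolved model specification.

## Statistics

* **Threshold exceedance** (Model 1): percentage of recorded time points at
  which the monomer count exceeds a threshold.  The comparator is strict
  (`count > threshold`) by default and configurable.  The strict convention
  is chosen because the Poisson stationary law pins the expected
  mean-versus-exceedance correlations at (threshold 1, normal rate) to
  0.83, (threshold 1, impaired) 0.84 and (threshold 4, impaired) 0.34 under
  the strict reading — matching the published statistics — whereas the
  inclusive reading gives 0.79/0.71/0.54, which matches none of them.
* **Mean-versus-exceedance regression**: ordinary least squares across
  cells with the textbook t-test on the slope (df = n−2) and Pearson's r;
  degenerate (zero-variance) inputs are rejected, not silently passed.
* **Prevalence curves**: cumulative percentage of cells associated with
  plaques by age, with the 95% band `±1.96·√(p(100−p)/N)` (p in percent,
  N cells).  The band collapses to zero at p = 0 or 100 by construction.
* **Curve shape**: a prevalence curve is classified `flat`,
  `linear` or `convex-increasing` by comparing residual sums of squares of
  a straight-line fit against a growing-exponential fit
  `A·(e^{ca} − 1)`; the label reports the better-supported form together
  with both fits.  This operationalises "linear increase" versus
  "exponential increase" without asserting a mechanistic functional form.

## Parameter scans

Single-parameter scans rerun independent ensembles per value and summarise
prevalence at a reference age (with the CI above), median lag time and mean
final plaque size over plaque-bearing cells.

The global calibration scan draws Latin-hypercube parameter sets:
`k_prod`, `k_deg` fixed at their measured values; `k_pf`, `k_pg`
constrained to [½, 2]× their experimentally anchored defaults; `k_dimer`,
`k_dedimer`, `k_pghalf`, `k_disagg` spanning two orders of magnitude
(decade below to decade above the default).  Marginals are log-uniform —
rates spanning orders of magnitude have no natural linear scale — with one
sample per equiprobable stratum.  The two-stage elimination then mirrors
the calibration procedure: stage 1 (normal clearance, small ensembles)
drops sets with more than 30% of cells plaque-associated by age 100; stage
2 (declining clearance, larger ensembles) drops sets below 10% at age 100
or above 15% at age 50.  Every decision is recorded with its measured
percentages in a JSON audit trail.  The *number* of sets surviving each
stage depends on the random design and is not a reproducible quantity; only
the rules are.

## Interventions

Interventions are expressed as model surgery plus one timed event, so the
treated process is bit-identical to the untreated one up to the
administration age (the experiment driver also reuses per-cell seeds across
arms, giving paired comparisons).

* **Anti-dimer antibody**: species `antiAbDim` (initially 0), zeroth-order
  antibody supply (rate 0 until administration), and second-order binding
  `antiAbDim + AbDim → ∅` at `1e-7 /molecule/s`.  At the administration age
  an event sets the antibody count to 1000 and the supply to `1e-7 /s`.
* **Anti-monomer antibody**: identical construction against `Abeta`, with
  the supply dose as the key free parameter — monomers are continuously
  produced, so a supply comparable to `k_prod` (two orders of magnitude
  above the anti-dimer dose) is needed for a lasting effect.
* **Production inhibition**: one event multiplying `k_prod` by
  `1 − f` (default f = 0.25).

Bound antibody–target pairs are removed to the sink: no unbinding and no
explicit complex species.  This is the simplest construction that exhibits
pool depletion (each neutralisation costs one antibody).  The transient dip
in plaque burden under monomer-directed antibodies needs no extra
mechanism: removing free monomers starves aggregate growth while
first-order disaggregation continues, so existing plaques shrink until the
antibody pool is titrated away.

## Default study conditions and problem sizes

The published calibration uses 500-cell ensembles, 100-year horizons and
500 record points.  Package defaults keep the horizon and grid; ensemble
sizes are per-experiment choices.  The test suite and the acceptance script
use 100–200 cells per arm (and 40–60 for multi-arm qualitative
comparisons), chosen so the whole suite runs on a desktop core in minutes
while keeping binomial confidence bands a few percentage points wide; all
comparisons against calibrated percentages are made CI-aware at those
sizes.

## SBML exchange

Models export to SBML Level 3 Version 2 with explicit MathML kinetic laws
equal to the stochastic hazards (substance units = items) and one SBML
event per timed event; import accepts Level 2 as well, infers hazard kinds
structurally from the MathML (symbolic matching, via sympy, against the
supported hazard vocabulary), and rejects anything else by name
(`UnsupportedRateLawError`) rather than approximating.  Round-tripping
preserves hazard semantics exactly; this is asserted on randomised states
in the test suite.  The writer/reader is a purpose-built subset
implementation on `lxml`.

## Known limitations

* No explicit trimers/oligomers/protofibrils; nucleation jumps straight
  from two dimers to an aggregate.  No spatial structure; one aggregate
  counter per cell rather than per-plaque identities.
* Lag times are grid-resolution (0.2 years), not exact first-passage times.
* Model 3 has no published calibration; its quantitative outputs should be
  treated as illustrative.
* The antibody construction ignores pharmacokinetics, affinity maturation
  and immune dynamics; "dose" is a supply rate, not a physical
  concentration.
* Ensembles model cell-to-cell variability only through intrinsic reaction
  noise — no extrinsic parameter heterogeneity between cells.
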