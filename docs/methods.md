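# Methods

## Model structure

A resource-allocation model couples a stoichiometric network to the
machinery that runs it. Species are partitioned into extracellular
species `Y`, internal metabolites `X`, storage polymers `C` and
macromolecules `P` (catalytic enzymes, the ribosome, and noncatalytic
*quota* compounds such as cell wall, membrane or bulk protein). Amounts
are molar (mmol), weights are g/mmol, time is hours, turnover numbers are
1/h and maintenance coefficients mmol/(g·h). Objective biomass is
`B_o = b_Pᵀ p`; total biomass adds the storage mass, `B_t = B_o + w_Cᵀ c`.
Objective weights `b_i` usually equal molecular weights `w_i` but may be
zero (e.g. secreted enzymes that should not count as growth).

Reactions are classified deterministically from the species they touch:
any contact with an extracellular species makes an exchange reaction;
otherwise producing a macromolecule makes a synthesis reaction; otherwise
touching storage makes a storage reaction; the remainder are metabolic.
A reaction coupling the environment directly to macromolecules or storage
is rejected as unclassifiable — such a step always hides an unmodeled
intracellular intermediate. Maintenance reactions are ordinary metabolic
reactions identified solely by a positive maintenance coefficient ψ; they
must be spontaneous.

### Constraint matrices

* **Capacity (`H_C`, `H_E`)** — one row per catalytically active enzyme:
  `Σ_{j ∈ cat(i)} v_j / kcat_j ≤ p_i`. Reversible fluxes are decomposed
  into nonnegative forward/backward parts `v = v⁺ − v⁻`, and the row reads
  `v⁺/kcat⁺ + v⁻/kcat⁻ ≤ p_i`, so a single linear row bounds both
  directions (the formulation must be linear, and the forward and backward
  turnover numbers may differ). `H_E` is a filter matrix with exactly one
  unit entry per row.
* **Quota (`H_B`)** — one row per quota species: `φ_s B_t − w_s p_s ≤ 0`.
  `B_t` inside this row uses objective weights for macromolecules and
  molecular weights for storage, exactly as in the biomass definitions;
  this means a macromolecule with `b_i = 0` does not count toward the
  quota baseline. That follows the biomass definitions literally; it is
  biologically arguable for secreted enzymes, and noted here as a
  deliberate choice.
* **Maintenance (`H_M`)** — one row per reaction with ψ > 0:
  `v_m ≥ ψ B_t`. The floor applies only to maintenance rows; all other
  fluxes are bounded below only by their box bounds.

## Dynamic optimization

The collocation scheme places amounts on the nodes of a uniform grid and
keeps fluxes piecewise constant on intervals; integrating constant fluxes
is exact, so the discretized dynamics are simply
`a_{k+1} = a_k + Δt·S v_k`. The default `implicit_euler` scheme enforces
capacity, quota and maintenance at the right node of each interval and
integrates the objective by right-endpoint quadrature; `trapezoid`
enforces capacity at both interval endpoints and uses trapezoidal
quadrature, roughly halving the discretization error at the same grid
(observed on the self-replicator benchmark). Nonnegativity is enforced at
the nodes only; between nodes it is a property of the discretization, not
a guarantee.

The LP is solved with scipy's HiGHS backend behind a minimal solve
contract (objective, primal values, status), with the primal feasibility
tolerance tightened to 1e-10 so returned trajectories satisfy
quasi-steady-state and path constraints to ≤1e-8 (asserted in the test
suite). Degenerate optima are common — flux patterns are
backend-dependent, so tests assert objective values and residuals, never
uniqueness of fluxes. Infeasible and unbounded problems raise distinct
exceptions and are never clamped.

On the one-enzyme self-replicator (`dp/dt = v ≤ k·p`), whose optimum is
`p(t) = p₀e^{kt}` with objective `(p₀/k)(e^{kT}−1)`, the implicit-Euler
objective error decreases monotonically with step doubling and is below
1% at 128 steps for `kT = 1`.

### Balanced growth initializer

Balanced exponential growth at rate μ requires every storage and
macromolecule pool to reproduce itself: `S_X v = 0`, `S_P v = μ p`,
`S_C v = μ c`, plus capacity, quota and maintenance, normalized to
`B_t = 1 g`. Feasibility in μ is monotone, so the maximal rate is found
by bisection (default bracket `[0, max kcat]`, default absolute tolerance
1e-6); the feasible composition is rescaled linearly to any requested
initial biomass. Extracellular amounts enter only as availability: uptake
of a species with zero amount is blocked, any positive amount is treated
as saturating — in balanced growth the rate limits come from enzyme
capacity, not substrate stock.

### Growth-rate diagnostics and the end-of-horizon switch

The instantaneous model growth rate on an interval is
`μ = ln(B_t(t_{i+1})/B_t(t_i)) / Δt`. Under saturating nutrients and a
balanced initial composition the interior of the optimal trajectory grows
at a constant rate equal to the balanced-growth optimum up to a
discretization bias of order `μ²Δt` (implicit Euler overestimates
geometric growth by one factor of `1/(1−μΔt)` per step). Near the end of
the horizon the finite-horizon optimum legitimately departs from balanced
growth: capacity that will never be used again is no longer worth
replicating, and production shifts into the cheapest objective-carrying
biomass (in the toy model, the structural quota compound). Constancy of
μ is therefore a property of the trajectory interior; tests check the
first quarter of the horizon and compare against the balanced-growth rate
with tolerance `2·μ²Δt`.

Experimental growth rates are fitted as the ordinary least-squares slope
of ln(OD) against time over all supplied points; restricting to the
exponential phase is left to the caller. When the fitted rate lies below
the model optimum, the maintenance coefficient ψ of a designated
ATP-hydrolysis reaction is tuned by bisection (μ is monotone decreasing
in ψ) until the simulated rate matches within tolerance; if the
experimental rate *exceeds* the model optimum at ψ = 0 the error message
points at the turnover numbers, which is where such a discrepancy
almost always originates.

## Builder conventions

* **Sequences** — standard multi-record FASTA via Biopython; `*` stop
  characters are stripped; ambiguity codes (B, Z, X, U) are rejected by
  default and mapped to the nearest standard residue only on request.
  Residue-to-metabolite naming is a configurable map (default:
  three-letter residue names) so any reconstruction namespace can be
  targeted.
* **Translation energy** — detailed mode charges, per residue, 1 ATP →
  AMP + PPi (charging) and 2 GTP → 2 GDP + 2 Pi (elongation). Lumped mode
  charges `atp_per_aa` ATP → ADP + Pi per residue for models that do not
  resolve GTP; the default of 4 counts the three hydrolysis events plus
  charging at equal cost and is overridable. Byproducts a model does not
  track can be dropped; consumed cofactors cannot.
* **Complexes and oligomers** — per-subunit residue counts are multiplied
  by the subunit copy number and summed; energy scales with the
  copies-weighted total residue count. Isoenzyme-catalyzed reactions are
  split into identical copies, one per enzyme, so every reaction has
  exactly one catalyst. Enzymes acting in several compartments are
  duplicated with deterministic compartment-suffixed ids
  (`FUM_cytosol`, transporters `ETrans2_e_c`).
* **Quota compounds** — biomass-reaction component coefficients are
  divided by `φ = Σ S_i w_i` so one quota unit weighs exactly 1 g;
  byproducts (e.g. uncharged tRNAs) carry zero net weight under the
  residue-mass convention, and weights are taken as given input where a
  reconstruction uses another convention. The protein quota is scaled by
  `(1 − f_e)`, the noncatalytic share from a quantitative proteomics
  dataset. Its ribosome-catalyzed synthesis gets a turnover number
  `3600·a / (Σ amino-acid coefficients)` in the non-standard unit
  1/(mmol·h), because one "unit" of the lumped reaction is a
  gram-normalized residue bundle rather than a single chain.
* **Turnover numbers** — observations are filtered to wild type; the
  enzyme-wise median (default) or mean is used. When no same-organism
  value exists the median over other organisms is the best available
  approximation; the fallback chain (own organism → other organisms →
  user default) logs each step.

## The toy model and other fixtures

The built-in toy model implements the reference 14-species/14-reaction
network verbatim: stoichiometries, turnover numbers (including the
asymmetric 25/30 storage reaction), the spontaneous maintenance reaction
and the reference initial amounts (N1 = O2 = 10, N = Stor = 0, R = 0.03364,
S = 0.7499). Quantities the reference tables leave open are exposed as
keyword parameters with documented fixture defaults, chosen once:
ψ = 0.01 mmol/(g·h), structural biomass fraction 0.3, N2 = 10 mmol,
0.001 mmol of each non-ribosomal enzyme (a strictly zero enzyme
complement would make any maintenance flux infeasible), and molecular =
objective weights equal to synthesis chain length / 1000 (1000 residues ≈
1 g/mmol). These are fixture choices, not reference values.

The protein-quota coefficient table shipped for testing is **synthetic**:
20 charged-tRNA coefficients built from the canonical yeast proteome
residue composition and average residue masses, scaled to the documented
yeast protein content of 0.466298 g per g dry weight. It reproduces
composition statistics, not any database entry, and exists so the quota
normalization can be exercised offline.

Random generators (builder inputs and full random models) are seeded and
reproducible; random model parameters are drawn on coarse decimal grids
so SBML serialization round-trips without any numeric tolerance.

What the synthetic fixtures do **not** emulate: genome-scale network
size (hundreds to thousands of reactions), realistic kcat heterogeneity
across pathways, compartmentalized eukaryotic networks, or measured
proteomics noise. Passing tests demonstrate correctness of the
construction rules, the serialization dialect and the optimization
machinery — not predictive accuracy on any real organism.

## Serialization dialect

SBML Level 3 Version 1 with fbc version 2 (`fbc:strict = false`; the
`fast` attribute is written as `"false"` until the Level 3 Version 2
target removes it). Every species carries a `ram:species` annotation
(namespace `https://www.fairdomhub.org/sops/304`) with its type; biomass
species add molecular weight, objective weight and biomass percentage.
Every reaction carries `ram:kcatForward`, `ram:kcatBackward` and
`ram:maintenanceScaling`. Numeric attributes are written as parameter
references (`weight_<species>`, `bp_<species>`, `kcat_fwd_<reaction>`,
`kcat_bwd_<reaction>`, `psi_<reaction>`, shared `zero`); the reader
accepts literals and references interchangeably. Catalysis is exactly one
`fbc:geneProductRef` per reaction — and/or association trees are outside
the dialect because complexes are pre-resolved and isoenzymes pre-split —
and reactions without an association are spontaneous. Gene-product labels
carry the complex recipe verbatim and are never parsed (fbc requires a
label, so an empty recipe is normalized to the gene-product id on write).
Nonlimiting extracellular species are the only ones with
`boundaryCondition="true"` (and `constant="true"` unless externally
driven). Initial amounts may equivalently be given as concentration times
compartment size. `ram:biomassPercentage` is always emitted (as `zero`
where it does not apply) but its absence is tolerated as 0 on read.
Unknown foreign annotations are carried through round trips opaquely; EC
numbers travel as MIRIAM `isVersionOf` annotations.

The validator reports located findings with stable rule codes; MUST-rule
violations are errors, and one enzyme species catalyzing reactions in
disjoint compartments is a warning (it is almost always an id collapse of
what should be two per-compartment enzymes).

## Known limitations

* Kinetic rate laws, regulation and concentration-based (volume-scaled)
  formulations are out of scope; so are cyclic-steady-state (cFBA) and
  ME-model variants and stochastic/robust extensions.
* tRNA charging, cofactors and prosthetic groups are not resolved in
  enzyme synthesis; they can be carried as quota compounds instead.
* Automated database retrieval (UniProt/BRENDA/SABIO-RK) and
  sequence-similarity-based turnover transfer are not included; turnover
  tables are user-supplied.
* Dynamic problems scale as (nodes × species + intervals × fluxes) LP
  variables; genome-scale networks are better reduced before dynamic
  simulation, while the balanced-growth initializer scales much further.
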