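# Methods

## Model representation

A network is N metabolites × M reactions. Column j of the sparse
stoichiometric matrix **S** holds reaction j's signed coefficients
(negative = consumed); the column is rebuilt from the reaction record on
demand, so the record is the single source of truth. Flux units are
mmol gDW⁻¹ h⁻¹ throughout; the biomass drain's flux is the growth rate in
h⁻¹. A reaction is reversible exactly when its lower bound is negative,
and an exchange is any single-metabolite pseudo-reaction, with negative
flux denoting uptake. Reactions without explicit bounds get the
conventional numeric infinity of ±1000 mmol gDW⁻¹ h⁻¹; this magnitude `B`
doubles as the detection level for unbounded loop flux (below).

GPR rules are immutable AND/OR trees over gene identifiers. AND nodes are
complex subunits, OR nodes isozymes; both require at least two children,
and a single gene is a leaf. The parser accepts case-insensitive
`and`/`or` (also `&`/`|`) with parentheses, OR binding loosest, matching
the common constraint-based-modeling convention; SBML FBC gene-product
associations are converted to the same tree via their infix rendering.

## Linear programming

FBA and FVA are solved with the HiGHS solvers behind
`scipy.optimize.linprog`. HiGHS is deterministic for a fixed model, so
repeated runs return identical extrema — the package exposes only FVA
extrema and one optimal FBA vertex, and nothing downstream depends on
which optimal vertex the solver picks. Infeasibility and unboundedness
are reported as solution statuses, never exceptions; only *pinned*
constraints that empty the polytope raise, and the error names the first
pin whose addition caused it (found by re-adding pins one at a time).

Numerical conventions:

* Flux equality comparisons use absolute tolerance 1e-6. With bounds of
  magnitude 1000, purely relative tests are fragile near zero.
* "FVA at maximum biomass" pins the biomass lower bound to
  `v_max · (1 − 1e-6)` rather than an equality, avoiding solver-level
  infeasibility from tiny optimality gaps.
* Gene deletion evaluates every GPR against the surviving gene set and
  closes (bounds [0, 0]) the reactions whose rule is false; reactions
  without a rule are never touched. Unknown gene ids warn and are
  ignored rather than raising, since expression platforms routinely
  carry ids absent from the model.

## Balance checking and repair

Element and charge imbalance is the coefficient-weighted sum of formula
counts and charges, products minus reactants. Metabolites with generic
R-group side chains are tallied as opaque `R`/`X` tokens: they must
cancel one-to-one across the reaction, and any residual marks the
reaction *unbalanceable* — flagged for a human, never auto-repaired, as
does any participant with no formula or charge.

Automatic repair is restricted to imbalances spanned by H⁺, OH⁻, and
H₂O. Those three species are linearly dependent (H₂O = H⁺ + OH⁻), so a
solution exists iff the imbalance satisfies H = charge + 2·O; the
canonical repair uses water for the oxygen deficit and protons for the
charge deficit, requiring integer counts. Anything else is returned as a
structured failure listing the offending elements. The helper species
are located in the metabolite table by formula and charge, and created
under conventional ids only if absent.

## Thermodynamically infeasible cycles

An internal loop that can carry flux with every exchange closed violates
energy balance. Detection closes all exchanges (bounds [0, 0]) — the
model itself is silent on this, but open exchanges would flag legitimate
uptake-to-product pathways as bound-hitting — and runs FVA with no
biomass constraint; a reaction is a candidate iff an extremum reaches
the infinity magnitude, |extremum| ≥ B − 1e-6.

The loops themselves are the null space of **S** restricted to the
candidate columns. The basis is extracted by rank-revealing Gaussian
elimination (reduced row echelon form) rather than an orthonormal SVD
basis: RREF ties each basis vector to one free column, keeping supports
sparse so that a duplicated reaction pair yields a clean support-2
vector. Vectors are normalized so their largest-magnitude coefficient is
+1 and reviewed smallest support first. A support-2 cycle whose two
stoichiometry columns are equal or negated entry-for-entry is an
*equivalent pair* (a duplicate reaction, resolved by deleting one copy);
anything else, including two-reaction candidates with mismatched
cofactors, is *multi_reaction* and needs a judgement call.

Gibbs free-energy records (ΔG ± error, kcal/mol) supply one mechanical
restriction: if the whole interval lies more than 4 kcal/mol below zero
the reaction becomes forward-only (lower bound raised to 0), above, it
becomes reverse-only. Bounds already consistent with the free-energy
direction are left alone, making the rule idempotent. Removal-versus-
restriction for multi-reaction loops is inherently a literature
judgement, so `curate_until_closed` takes an explicit ordered action
list, applies every action, re-detects after each, and reports any
surviving cycles instead of silently dropping them.

## Expression mapping

The fold change `c_j` is computed level-then-ratio: combine control
levels over the GPR (min over AND, sum over OR), combine stress levels
the same way, and divide. Combining per-gene fold changes first would
make the isozyme sum meaningless (a sum of ratios is not a ratio), so
the level convention is the only self-consistent reading. Consequences:

* `c_j` is invariant to global rescaling of both profiles (verified as
  an exact property).
* Missing genes and zero control levels yield the neutral `c_j = 1` —
  missing data must not invent regulation, and an infinite up-fold is
  inert anyway because values ≥ 1 never tighten bounds.
* An optional significance mask (from upstream differential-expression
  statistics, which this package does not compute) replaces unmasked
  genes' stress levels with their control levels.

## Core-set extraction

Step 1's FVA runs with nutrient-uptake limits in force but no biomass
constraint: the resulting ranges are the loosest attainable bounds, so
only contraction (c_j < 1) can matter. The contraction `[L·c_j, U·c_j]`
is applied verbatim to both ends, including forced-flux reactions with a
positive lower bound — the rule is unconditional, and the usual remark
that the lower bound only moves for reversible reactions merely
describes the common case. Reversible reactions get a single `c_j` for
both directions; no per-direction rule exists to implement. Inactive
reactions keep their original model bounds (not their FVA bounds — the
feasible set is identical either way, and fewer overrides mean fewer
numerical surprises).

Each iteration k: contract bounds with the current fold changes; FBA on
both models; relative attenuation `(v_UR − v_R)/v_UR` (relative, not
absolute — the 2% threshold only makes sense against the unregulated
optimum); FVA on the regulated model at its pinned optimum; a
down-regulated reaction joins the core set iff its achieved range
attains the imposed bound at *either* end, to tolerance
`max(1e-6, 1e-6·|imposed|)` (exact equality being meaningless in
floating point). The core set of a sub-threshold iteration is still
computed and recorded, flagged `biomass_effect="minimal"`, before
iteration stops — minimal-effect sets are part of the hierarchy's
reporting surface even though they no longer shape metabolism. Core
members' `c_j` are then reset to 1 and the loop repeats, to a default
ceiling of order 6.

`verify_core_sufficiency` re-derives everything from scratch (it shares
no intermediate state with the run it checks): two bound sets from the
unregulated ranges — all active reactions contracted versus core members
only — each FVA'd at its own pinned biomass optimum, compared
elementwise at tolerance 1e-6.

## Scenarios

`ScenarioConfig` is declarative: phase, growth pin (a rate, `"max"`, or
none), nutrient bound overrides, blocked reactions, gene deletions,
extra reactions, and a redox-free flag. An empty config is a no-op
(plain FVA), asserted as an identity test. Presets ship as YAML with the
growth-rate pins used across the validation conditions (0.52, 0.47,
0.32, 0.18, 0.184, 0.182, 0.17, 0.07 h⁻¹) but placeholder reaction ids,
since exchange namespaces are model-specific.

The redox-free variant adds reversible unbounded NAD ⇌ NADH and
NADP ⇌ NADPH interconversions, consuming one proton with the hydride
when a proton species exists so H and charge stay balanced; the electron
balance is deliberately open — that is what removing the redox
constraint means. Cell-recycle nutrient limitation sets each exchange's
lower bound to a fraction (default 80%) of its most negative attainable
flux at the wild-type growth optimum. Yield spaces grid the products'
FVA ranges at a pinned growth rate; at each grid point the substrate
uptake is minimized (the exchange flux, negative for uptake, is
maximized) and yields are product flux over minimal uptake magnitude,
with infeasible points flagged and zero-uptake points marked degenerate
rather than dropped. Measured-flux comparison is plain interval
arithmetic with the distance to the nearest endpoint for outliers.

## Synthetic fixtures and oracles

The toy generator builds exchange → transport → mandatory trunk →
parallel branches → biomass, with unit stoichiometry so every optimum is
hand-computable (max growth = uptake / branch count) and GPR styles
cycling through single genes, two-subunit complexes, and isozyme pairs.
Metabolite formulas are single-token (`X`), making balance checks exact
by construction; exchange and biomass pseudo-reactions are exempt from
balance, as in any real model.

Planted regulation inverts the GPR semantics: an OR target scales every
isozyme (the sum scales exactly), an AND target scales only the
lowest-expressed subunit (still minimal after scaling down), recursing
through nesting. Realized fold changes are re-verified at generation
time, as is the requirement that every target carries forced flux at the
pinned biomass optimum — a target off the optimal pathway could never
bind and would make recovery vacuous.

The LP-free oracle enumerates the vertices of {S v = 0, lb ≤ v ≤ ub} as
basic feasible solutions: every choice of M − rank(S) variables fixed at
a bound with the rest solved from the mass balance, feasibility-checked
at 1e-9. With all bounds finite the polytope is bounded, so every linear
objective attains its extrema at an enumerated vertex; the ceiling of
~12 reactions keeps full enumeration under a second. Random loop
fixtures plant either a duplicate-reaction pair or a directed 3–5 cycle
in an acyclic scaffold whose other reactions cannot carry flux once
exchanges close, so the planted loop is exactly the ground truth.

What the fixtures do not emulate: genome-scale degree distributions,
compartmentalization beyond one cytosol plus a boundary, realistic
microarray noise, or GPRs deeper than two levels. Passing the suites
therefore demonstrates correctness of the algorithms under their stated
assumptions, not calibration against any particular organism's data.

## Problem sizes

The validation workloads are sized for a desktop single-core run: 50
random networks of 6–10 reactions for the LP-versus-enumeration check,
52 loop fixtures for cycle detection, 200 randomized profiles × 4 tree
shapes for the fold-change identities, and 100 seeded single-bottleneck
fixtures (5–14 reactions) for recovery and sufficiency. The full test
suite completes in under a minute; `scripts/acceptance.py` in well under
two.

## Known limitations

* Core-set identification tests bound attainment at the FVA extrema;
  degenerate alternate optima that touch a bound without that bound
  being *necessary* would be included (observed on none of the fixtures,
  but not excluded in principle).
* The attenuation hierarchy is not guaranteed monotone in k and the
  package deliberately does not assert it.
* Rebalancing never proposes hydroxide on its own; any imbalance
  expressible with OH⁻ is equally expressible with H₂O − H⁺, so the
  canonical solution is unique only up to that exchange.
* `normalize_fluxes` on range maps uses the reference range's
  largest-magnitude endpoint, which is only meaningful when the
  reference exchange is pinned or near-pinned.
* The tabular format stores no compartment topology beyond the
  per-metabolite label.
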