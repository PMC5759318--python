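# Methods

## Scope and model

`halogem` analyzes compartmentalized genome-scale metabolic models under the
standard constraint-based assumptions: steady state (S·v = 0, no metabolite
accumulation), capacity bounds per reaction flux, and a biomass
pseudo-reaction whose flux is the specific growth rate μ in h⁻¹. Metabolite
ids carry a bracketed compartment suffix (`glc-d[c]`, cytoplasm/periplasm/
extracellular); exchange reactions are written outward-positive, so uptake
is a negative flux. Formulas and charges (fixed at pH 7.2 during curation of
the source reconstruction) are carried as data and never recomputed.

Models round-trip through two formats: SBML Level 3 with fbc bounds, gene
products and objectives (via python-libsbml; subsystem and reaction kind are
stored in the reaction notes body), and a two-table TSV dialect
(`reactions.tsv`, `metabolites.tsv`, `model.json`) with a canonical
stoichiometry string (`-1 a[c] + 1 b[c]`). Identifier characters outside the
SBML SId alphabet are escaped reversibly (`__<ordinal>__`), so arbitrary
bracketed ids survive the SBML round trip exactly.

## Biomass formulation

A biomass composition is macromolecule mass fractions (g gDW⁻¹) plus molar
monomer ratios per group. Amino-acid ratios follow the equal-expression
assumption (each annotated protein contributes once to the pooled residue
count); deoxyribonucleotide ratios come from genomic G+C via Chargaff
pairing (dG = dC = GC/2); ribonucleotide ratios are a weighted rRNA/tRNA/mRNA
mix whose pool proportions are configuration (default 0.83/0.14/0.03, the
classic exponential-growth RNA census — the source tables only say the
proportions were "defined previously", so the default is explicit
configuration, not a constant). Monomer coefficients are
−fraction/(Σ ratio·weight) · ratio, which makes Σ|coeff|·weight reproduce
each group's mass fraction to 1e-6.

Growth-associated maintenance is GAM = base + polymerization cost with the
tabulated two-decimal values (36.94; 23.04 low / 8.79 high salinity). The
sum is computed in integer cents (Decimal), so reports print 59.98 and 45.73
with no float drift. The GAM term is written ATP + H₂O → ADP + Pi + H.
Compatible solutes (ectoine-like) enter the biomass with condition-specific
mmol gDW⁻¹ coefficients; switching conditions changes coefficients only,
never the metabolite set of the energy term.

## FBA layer

The LP is solved with HiGHS through `scipy.optimize.linprog`
(feasibility tolerances 1e-9 requested; results validated downstream at
1e-6). Only the objective value is canonical: flux vectors at the optimum
may be degenerate and are reported as one optimal solution among possibly
many. Infeasible/unbounded are statuses, not exceptions.

A `ConditionSpec` bundles the biomass choice, exchange-bound overrides, and
fixed fluxes; ATPM is fixed at both bounds (7.6 mmol gDW⁻¹ h⁻¹) because
upkeep is an obligatory drain, not a minimum. "No growth" means
μ < 1e-6 h⁻¹ everywhere (screens, essentiality). Gene deletions propagate
through the GPR rules (AND = complex, broken by any subunit loss; OR =
isozymes, rescued by any member); reactions whose rule evaluates false are
closed to zero flux before re-optimizing. ATP yield per substrate pins
biomass to zero, fixes the substrate uptake at both bounds, and maximizes
the maintenance hydrolysis flux.

## Gap analysis

Root no-production/no-consumption metabolites are read off the sign pattern
of S after splitting reversible reactions into two directions. Capacity
(blocked) testing replaces the monolithic MILP formulation with one LP per
metabolite — a temporary sink (or source) is added, all exchanges are
opened, and its flux is maximized; capacity ≤ 1e-8 means blocked. The
identical blocked-set semantics at far lower dependency cost is the reason
for the substitution. Both conventional mass-balance options are exposed:
`strict` (S·v = 0 on every row) and `relaxed` (accumulation allowed:
S·v ≥ 0 for production tests, ≤ 0 for consumption tests). Downstream/
upstream gap sets are blocked sets minus root sets. Note that under strict
balance, conserved cofactor pools (ATP/ADP, NAD/NADH) are unproducible by
construction; the relaxed mode is the one that matches graph-reachability
intuition and is what the test oracle checks.

## Flux sampling

Equality constraints (stoichiometry plus fixed-flux reactions) are reduced
by an orthonormal null-space basis to v = v₀ + N·α; the bound constraints
make the α-polytope full-dimensional. Two samplers share the projection:

* **Rejection** (reference): α drawn uniformly over the polytope's bounding
  box (obtained by 2d LPs), back-calculated to fluxes, rejected on any bound
  violation. Guarded at ≤ 6 dimensions and an acceptance floor of 1e-6 — the
  literal method degenerates at scale and is retained only as the oracle.
* **Coordinate hit-and-run** (production): from a Chebyshev-center start,
  pick a random independent coordinate, compute the feasible segment, jump
  uniformly; warmup 1000 steps, thinning 10. The stationary law is uniform
  on the polytope; the suite checks its marginals against the rejection
  oracle by KS tests at α = 0.01 on ≤ 3-D fixtures. Warmup/thinning are not
  specified by the source protocol; the defaults are recorded in every
  sample set's metadata so results remain auditable.

Randomness is a counter-based Philox generator keyed by an explicit seed;
a fixed seed reproduces the sample matrix bitwise. Every returned sample is
validated (S·v = 0 within 1e-6, bounds within 1e-9) before use; float-level
boundary overshoot is clipped to the bounds. Medians are normalized by
|median glucose uptake|, so the glucose exchange itself normalizes to −1.
The default target of 20,000 valid points is scaled to 2,000–5,000 in tests
and drivers purely for runtime; nothing in the statistics depends on the
scale beyond the usual √n noise.

## Condition comparison

Per reaction, a two-sample Wilcoxon rank-sum with tie-corrected normal
standardization; Z is the deviate of the *second* (high-salinity) sample's
rank sum, so swapping arguments negates Z and "difference = high − low"
holds throughout. The selection bar |Z| > 50 with p < 0.01 sits far outside
null fluctuation at n ≈ 20,000 (null |Z| rarely exceeds ~4), so no
multiplicity correction is applied by default; Benjamini–Hochberg q-values
are emitted as an optional column. Effect sizes are the mean of k = 2000
random subtractions with indices drawn without replacement independently per
condition — the source protocol does not state a pairing, and with
independent sample sets any pairing is arbitrary, so the estimator targets
the difference of marginal means.

## Correlation modules

Spearman's ρ over sampled flux vectors (scipy), thresholded at |ρ| ≥ 0.7
with the boundary included; zero-variance (constraint-pinned) columns are
excluded with a warning rather than yielding NaN edges, and constancy is
detected by exact zero range, not a float-std cutoff. Modules are connected
components of the thresholded graph — the source analysis identified
clusters visually in a network viewer, and components are the assumption-free
formalization; a greedy-modularity alternative is provided but labelled
non-reference. Exports: GraphML, SIF, edge-list and module TSVs.

## Synthetic fixtures and what green tests establish

The core toy is a 3-compartment network: periplasmic glucose transport
(porin gene, then a two-subunit complex), ≥ 2 catabolic routes whose
ATP/NADH yield halves per route (EMP/ED-like redox contrast), a lumped TCA
loop (1 ATP + 4 NADH + 3 CO₂ per pyruvate), P/O-2 oxidative phosphorylation,
and an osmolyte synthesized from pyruvate + 2 ATP, drained by two biomass
reactions with coefficients 0.1 (low) / 0.5 (high) mmol gDW⁻¹ and excretable
through an exchange that the salinity conditions close. With those numbers
the binding resource is ATP and the optimum is exactly

    μ* = (24·G − ATPM) / (14 + 11·e)

(G glucose uptake, e osmolyte coefficient), derived from the mass balances at
generation time and verified against the LP and against exact rational
vertex enumeration. The generator also records flux-coupled reaction pairs
(for correlation tests) and the essential-gene set, including the
initially non-obvious fact that the TCA complex genes are essential: without
the loop the routes plus respiration supply at most 3(1+e) ATP per unit
growth versus a (5+2e) demand.

Condition pairs can pin growth (default 1.0 h⁻¹), which constraint-fixes the
osmolyte flux at e·μ and makes the planted between-condition shift exact
((e_high − e_low)·μ = 0.4), so shift-recovery tests need no stochastic
tolerance. The 4-independent-pathways fixture gives a k-dimensional box
polytope with perfect within-pathway coupling, hence exactly k correlation
modules. Random ±1 networks (supply + spanning chain + drain + random
internal edges) are feasible by construction and stoichiometrically simple,
which is what makes the BFS reachability oracle exact for the relaxed gap
mode and keeps vertex enumeration tractable.

What the fixtures do **not** emulate: elemental balancing of lumped
reactions, realistic cofactor diversity, thermodynamic direction
constraints, or the 1530-reaction scale of a real reconstruction. A green
suite therefore establishes algorithmic correctness against independent
oracles, not biological realism of the toy numbers; organism-level numbers
(growth 0.43/0.19 h⁻¹, 195+8 essential genes, 27+71 dead ends, 549/461
correlation edges) are only checked when a user supplies the published model
under `data/`, and the published fraction "11.17% blocked" is reported
alongside raw counts rather than forced to agree with 98/1123.

## Numerical choices

* LP: HiGHS, requested feasibility 1e-9; downstream validation 1e-6.
* Growth epsilon 1e-6 h⁻¹; blocked-capacity tolerance 1e-8.
* Sampling validity: steady state 1e-6, bounds 1e-9 (clip-then-validate).
* Spearman threshold ties at exactly 0.7 are included.
* GAM arithmetic in integer cents; all other arithmetic in doubles.
* Seeds: Philox counter-based; derived sub-seeds stay below 2³¹.

## Known limitations

No flux-variability analysis, MOMA/ROOM, double deletions, expression
integration, gap filling, thermodynamic sampling, or exact polytope volume
(only sampling). The rejection sampler is intentionally unusable beyond 6
dimensions. Connected-component modules can merge visually distinct
clusters joined by a single strong edge; the modularity option exists for
that case but is not part of the reference procedure.
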