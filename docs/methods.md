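# Methods

## Model

The package analyses a metabolic network given as a stoichiometric matrix
`S` (m metabolites × n reactions) under the steady-state assumption
`S·v = 0`, directionality/bound constraints `v_min ≤ v ≤ v_max`, and a
growth medium expressed as upper bounds on the uptake direction of exchange
reactions. Proliferation enters as a biomass pseudo-reaction draining
precursors in measured proportions; its flux is the growth rate (1/h).
Fluxes are in mmol/(gDW·h) everywhere (note 1 µmol/(mgDW·h) is numerically
identical).

**Biomass.** Mass-type components (g/gDW) convert to molar coefficients as
`1000 · fraction / MW` with MW in g/mol; molar components (mmol/gDW) pass
through. The reference composition budgets 0.78 g/gDW amino acids,
0.06 g/gDW nucleotides and 0.16 g/gDW lipids (closing to 1.00 g/gDW; the
builder warns beyond 5% departure) plus a growth-associated maintenance of
24 mmol ATP/gDW, added as ATP + H₂O → ADP + Pi + H⁺ hydrolysis. The GAM is
treated as *additional* to the mass budget (standard practice; an ATP
drain adds no dry mass). Essential precursors the network cannot make are
assumed to flow from the medium straight into biomass; a matching
exchange+transport path is created when absent.

**Solvent capacity.** The enzyme mass sustaining flux `v_i` is
`v_i · MW_i / kcat_i` (MW in mg/mmol, kcat in 1/h). Summed over all
enzyme-catalysed reactions it is bounded by `C = 0.078 mg/mgDW`, the
product of the protein dry-mass fraction (0.779 mg/mgDW) and the metabolic
share of expression (0.1) — `compute_cap` reports the product rounded to
3 decimals and uses the unrounded value internally. Because fluxes are per
gDW while C is per mgDW, cost coefficients carry a fixed 10⁻³ scale.
Exchanges, the biomass pseudo-reaction and explicitly flagged
spontaneous/diffusion steps are exempt; transporters are *not* exempt by
default. Reversible reactions are split into two unidirectional halves
(both inheriting the enzyme parameters) so the constraint acts on
non-negative fluxes. Cap groups generalise the single global budget to
per-compartment budgets (membership by `compartment_tag`); compartment
caps must be user-supplied.

**kcat/MW assignment.** Tables keyed by reaction id and/or EC number are
resolved per reaction with source precedence human wild-type > non-human
wild-type > SABIO-style entries, taking the *maximum* within the winning
category. Unmatched reactions receive the median of the resolved known
kcats — one value per reaction before taking the median, so duplicated
table rows cannot shift it, and an even count averages the central pair.
Missing molecular weights get the median known MW. Isozymes/complexes are
not distinguished: gene associations are flat lists and per-gene enzyme
concentrations sum over a gene's reactions, which double-counts reactions
shared between genes (documented, deliberate).

## Solver

All programs are LPs solved with scipy's HiGHS backend (feasibility
tolerance 1e-9; reporting tolerance 1e-6). Infeasibility and unboundedness
are reported as solution status, not exceptions. Because alternate optima
are the rule in these models, every headline flux (lactate, O₂) is
reported as an FVA range — min and max subject to all constraints plus
`growth ≥ fraction · optimum − 1e-9` (the absolute slack avoids empty
feasible sets from round-off). The crowding-FBA objective is the biomass
*rate*; yield is computed afterwards as rate / glucose uptake.

## Growth sweep and phase detection

The glucose uptake bound is swept from 0 to the saturating uptake, found
by doubling until marginal growth vanishes and then bisecting (growth is a
concave, non-decreasing LP value function of the bound, so the plateau
predicate is monotone). Default grid: 100 uniform points. The zero-uptake
point carries the analytic yield limit — the stoichiometric maximal yield,
since the cap cannot bind as uptake → 0 — rather than 0/0. Without a cap
growth never saturates, so stoichiometric-only sweeps require an explicit
grid end.

Phase boundaries, as fractions of maximal growth:

- **I/II**: the largest growth fraction whose yield is within 1% (relative,
  `yield_tol`) of the sweep's maximum — the end of the optimal-yield
  regime. Alternatives (cap-activation point, O₂ inflection) were
  considered; yield departure is the most direct operational reading of
  "optimal-yield phase" and coincides with cap activation on the bundled
  fixture.
- **II/III**: the smallest growth fraction whose *FVA lactate minimum*
  exceeds `epsilon_lactate` (default 1e-6 mmol/(gDW·h)) — lactate
  secretion is necessary, not merely possible. Sweeps where lactate is
  never necessary (the uniform-cost control) report boundary 1.0 with a
  `no_phase_III` flag.

Grid round-off can put yield departure marginally after lactate onset; the
I/II boundary is clamped to the II/III one to preserve ordering. Sweep
TSVs carry both absolute lactate/O₂ ranges and ranges normalised by the
instantaneous glucose uptake.

## Two-strategy geometry

The reduced picture — strategy A (yield `Y_A`, enzyme cost `C_A` per
glucose) vs. B (`Y_B < Y_A`, `C_B < C_A`) under uptake bound U and budget
C — is solved exactly by enumerating the ≤ 5 vertices of the 2-D polytope
`{u ≥ 0, u_A+u_B ≤ U, C_A u_A + C_B u_B ≤ C}`. Ties break toward larger
`u_A`, so the glucose-limited regime reports the pure-A solution. With
ample glucose the winner is decided by the yield-to-cost ratios
(`0.094/0.302 ≈ 0.31` vs `0.035/0.050 = 0.7` for the reference values: B
wins). A brute-force grid search over (u_A, u_B) serves as the oracle in
tests.

## ACHR sampling

Warmup points come from per-reaction min/max LPs (2 per reaction, capped
at 2000 points, with the growth-fixing half-space included). Each step
picks the direction from the running center through a random warmup point
(differences of feasible points stay in null(S), so equalities hold
exactly), computes the chord limits against the box bounds and all
half-spaces (caps and growth fixing enter as ordinary rows, no special
casing), and samples uniformly on the chord; the center is the running
mean of all chain points. Default thinning keeps every 100th step (tests
use lighter thinning on the tiny fixture). Degenerate chords (< 1e-12) are
resampled with a retry cap; a fully determined flux space returns its
unique point. Everything is deterministic given the seed. The
coordinate-wise median of a sample set is *not* mass-balanced in general;
its ‖S·median‖∞ residual is reported. Pathway activity is the mean of the
members' absolute net median fluxes. No convergence diagnostics beyond the
constraint-satisfaction checks are provided.

For pathway comparisons across phases, operating points default to the
detected phase midpoints, realised by pinning the glucose bound to the
uptake achieving that growth and sampling near that point's optimum.

## Expression correlation

Per-gene enzyme concentrations (`v_i · MW_i / kcat_i`, summed over a
gene's reactions) are rank-correlated (Spearman, average ranks for ties)
with each column of a genes × samples expression matrix; columns sharing
fewer than 3 genes are skipped. Two models' per-column correlations are
compared with a paired two-sided Wilcoxon signed-rank test. Genes with
zero predicted concentration in both models are kept by default
(`drop_all_zero` exposes the alternative).

## Synthetic data

**Toy network.** Central carbon metabolism reduced to its decision
structure: glycolysis (glc + 2 ADP + 2 Pi + 2 NAD⁺ → 2 pyr + 2 ATP +
2 NADH), lactate dehydrogenase + export, a lumped respiration reaction
(pyr + NADH + 3 O₂ + 15 ADP + 15 Pi → 3 CO₂ + NAD⁺ + 15 ATP; so full
oxidation returns 2 + 2×15 = 32 ATP per glucose and fermentation 2), an
ATP demand, and a biomass reaction consuming 10 ATP + 1 pyruvate + 1 NADH
per unit. Biomass consumes NADH (anabolic reducing power) so that carbon
drain leaves the redox balance closed — without it, pure respiration would
be stoichiometrically impossible at nonzero growth and the
stoichiometric-only control could not stay lactate-free. Protons are
omitted (pseudo-balancing); LDH is kept reversible to exercise splitting.

Default enzyme parameters: ~36 kDa enzymes at kcat 1/s for glycolytic and
transport steps (cost coefficient 0.01), and a lumped 3.6 MDa respiratory
"machine" at 0.25/s (cost 2.0) — the mass aggregates the TCA +
electron-transport + ATP-synthase machinery per unit of lumped flux, which
is what the cost coefficient of a lumped reaction must carry. With the
default biomass demands this gives respiration yield 1.28 and cost 1.50
per glucose (ratio 0.85) vs fermentation 0.20 and 0.056 (ratio 3.6) — the
overflow-generating configuration. The cap defaults to 0.078 mg/mgDW, the
same budget used for genome-scale runs. Because the asymmetry is carried
by the molecular weights, redrawing kcats from the fixture's empirical
known-kcat set can never invert the ratio ordering — the robustness the
kcat-resampling simulations verify. The uniform-cost variant sets every
coefficient equal, under which respiration dominates at all uptakes and no
lactate is ever secreted.

The amino-acid variant adds glutamine/glutamate/alanine exchanges,
transporters, a lumped transamination step (GDH, deliberately costlier
than a transporter at 0.05 — biosynthesis machinery vs. a single carrier),
the ATP-consuming glutamine synthetase, and glutaminolysis; biomass then
also drains 0.5 glutamine per unit. Glucose-only growth must synthesise
glutamine (paying transamination + 1 ATP), medium glutamate spares the
first step only, and medium glutamine spares both — producing the
glutamine > glutamate > alanine gain ordering, amplified under the
capacity constraint.

**Kcat resampling** keeps a seeded fraction of the known kcats and redraws
every other non-exempt kcat uniformly from the empirical known
distribution (or the median of the retained ones); molecular weights are
untouched, mirroring robustness-to-kinetic-noise simulations.

**Synthetic sweeps** are piecewise curves with known boundaries (flat
maximal yield to b₁, linear decline after; lactate minimum zero to b₂,
ramping after, with lactate *possible* earlier via the FVA maximum) and
optional Gaussian yield noise — the unit fixture for the phase detector.

**Synthetic expression** uses a Gaussian copula: columns are
`r·z + √(1−r²)·ε` with z the normal scores of the concentration ranks and
`r = 2 sin(π·ρ/6)`, the Pearson parameter giving Spearman ρ for bivariate
normals. Calibration is exact in population; recovery tests run at
1,269 genes × 60 columns.

### What the generators do and do not emulate

The toy network reproduces the *decision structure* (yield-vs-cost
competition under a shared budget) and the textbook ATP accounting, not
genome-scale properties: its phase I/II and II/III boundaries coincide
(two effective strategies ⇒ yield departure and lactate necessity happen
at the same uptake, at growth fraction ≈ (Y_A/C_A)/(Y_B/C_B) ≈ 0.24 of
max), whereas a genome-scale network's many intermediate strategies
separate them and produce a distinct rising-O₂ phase II. Passing tests
therefore demonstrate the mechanism and the code paths, not the
genome-scale boundary values — those are properties of a full
reconstruction plus curated kcat/MW tables, which are drop-in inputs but
not bundled. Likewise the NCI-60-style correlation analysis is exercised
only on calibrated synthetic matrices.

## Numerical choices and limitations

- LP backend: scipy/HiGHS only; any alternative backend must pass the
  same invariant suite (determinism, crowding never raising the optimum,
  scale invariance).
- Infinity sentinel 1000 mmol/(gDW·h); reversibility follows bounds, not
  SBML flags, when they disagree.
- Uptake sign: exchanges are written `metabolite_external →`, uptake is
  negative flux internally, positive magnitude in every user-facing
  number.
- No GPR boolean logic (flat gene lists), no thermodynamic loop removal,
  no quadratic objectives, no live kinetic-database querying, and no
  enzyme-*volume* variant of the capacity constraint (the mass form is
  used throughout).
- Problem sizes in tests and the acceptance script are desk-scale by
  design: sweeps of ≤ 100 points, ≤ 50-resample robustness runs, sampler
  chains of a few thousand steps.
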