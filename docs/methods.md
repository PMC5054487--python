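# Methods

## Model

Two bacterial populations (relative sizes `n1 + n2 = 1`, total cell count
`N`) share one linear biosynthetic pathway

    S -> X_1 -> ... -> X_m -> P        (m + 1 reversible synthesis steps)
    P -> biomass                       (irreversible consumption)

inside a common host compartment. Every quantity is in dimensionless
model units; the canonical parameterization sets all kinetic constants to
one, `[S] = 10`, `n1 = n2 = 1/2`, cell demands `J_P,1 = J_P,2 = 1` and
host demand `J_P,0 = 0`.

Synthesis steps follow reversible Michaelis-Menten kinetics; only the
first step is feedback-inhibited by the end product P, by default
uncompetitively (the whole rate is scaled by `1/(1 + [P]/K_I)`; in the
limit `1/K_I -> 0` the uninhibited law is recovered). A competitive
variant adds `[P]/K_I` to the saturation denominator instead — the
standard competitive form, chosen because it reduces to the same
uninhibited limit. Intermediates and product cross membranes by
first-order diffusion `U = D([c]in - [c]out)` (no transporters:
endosymbionts are transporter-poor, and biosynthetic intermediates rarely
have dedicated carriers). The substrate S is buffered and carries no
balance equation. `N` multiplies the extracellular balances only and
cancels at steady state; it is exposed but irrelevant to all optima
(asserted in tests).

Intracellular balances are per cell; extracellular balances weight the
exchange fluxes by population fractions, and extracellular P carries the
host consumption `-N J_P,0`. Extracellular concentrations of species with
`D = 0` are not dynamical variables (their exchange flux is identically
zero); they are carried for bookkeeping only.

## Optimization

The allocation problem minimizes the population-weighted total enzyme
concentration `C = sum_i sum_alpha n_i [E_alpha,i]` subject to steady
state of every balance, `V_P,i >= J_P,i`, the host demand, and
nonnegativity. Rather than imposing the steady-state balances as
nonlinear equality constraints, they are eliminated analytically:

1. exchange closure fixes the extracellular levels,
   `[X_k]out = n1 [X_k,1] + n2 [X_k,2]` and
   `[P]out = n1 [P_1] + n2 [P_2] - J_P,0 / D_P`;
2. the chain balances determine every synthesis flux by back-substitution
   from the consumption fluxes, `V_{r-1},i = V_r,i + U_{X_r,i}`;
3. each enzyme level is then flux divided by the per-unit-enzyme rate,
   `E = V / eff(c)`.

What remains is a small inequality-constrained program over the log
intracellular concentrations plus the two consumption fluxes
(`2(m+1) + 2` variables), solved with SLSQP. Steady state holds exactly
by construction; every accepted solution is nevertheless re-verified
through the independent balance-residual path (rate laws evaluated at the
reported enzymes and concentrations; max-norm tolerance 1e-8, observed
~1e-15).

The search is restricted to forward-operating solutions: every synthesis
step must have positive thermodynamic driving force (`eff >= 1e-9`) and
nonnegative flux. Running a step backwards consumes enzyme without
serving any demand and is never cost-optimal; the restriction removes the
sign-degenerate regions of the `V/eff` ratio. An independent brute-force
oracle (grid search over enzyme space with root-finding for the steady
state, no such restriction) agrees with the solver within 2% in tests.

Numerical safeguards, chosen after the raw ratio `V/eff` proved
unbounded below on the m = 5 chain (line searches escaped to -1e12
through transiently infeasible regions):

* each concentration is bounded above by 1.05x its running-equilibrium
  cascade level (every feasible point satisfies `[B] < K_eq [A]` step by
  step, so the cap excludes no feasible point);
* the solver-facing cost clamps the efficacy denominator at 1e-3 (no
  optimum can sit below that: an enzyme with `eff < 1e-3` carrying a
  demand-scale flux would alone cost ~1e3 demand units) and passes
  negative fluxes through a C1 exponential hinge saturating at
  `-0.1 (J_P,1 + J_P,2 + J_P,0)`;
* near any optimum the surrogate coincides with the true cost and is
  smooth through `V = 0`, so split optima (one cell's head flux exactly
  zero) are ordinary KKT points; candidates are ranked by the true cost.

The landscape has coexisting local optima (symmetric and split branches).
`multistart` therefore runs a seeded portfolio: log-uniform random starts
(shared random cascade per cell pair, inter-cell gaps capped per species
at `~flux/(D n)` so permeable species start nearly equalized), plus
deterministic structured starts — one symmetric profile and one split
profile per candidate breaking point, encoding the physical structure of
a split optimum (gaps only on the handoff intermediate and the product).
Feasible SLSQP stalls (statuses 8/9) enter the candidate pool; selection
is by cost. Defaults: 24 starts, tolerances `ftol = 1e-12`, constraint
tolerance 1e-7. Enzymes below 1e-6 of the total cost are reported as
exact zeros; asymmetries `A_alpha` use the thresholded values and are
defined as 0 (flagged "both absent") when an enzyme is missing from both
cells. At a regime boundary (symmetric and asymmetric branch costs equal
within 1e-5 relative) the symmetric solution is reported with a boundary
flag, making output deterministic near the transition line.

Because the problem is mirror-symmetric when the two cells have equal
demands and fractions, asymmetric solutions come in +/- pairs; by default
the search is restricted to `[E_S,1] >= [E_S,2]` (`A_S >= 0`). The
restriction is lifted automatically in the demand-asymmetry and
population sweeps, where breaking the cell symmetry selects a genuine
orientation (large demand asymmetry drives the *reversed* complete split
`[E_S,1] = [E_X,2] = 0`).

The dual formulation (`maximize_flux_under_budget`) maximizes a uniform
demand-scaling factor lambda under a total-enzyme budget; at budget C*
it achieves lambda = 1 (same KKT system), which the tests assert.

### Exactness of the demand-scaling law

Optimal cost scales exactly linearly in the demands whenever the optimal
exchange fluxes vanish: all fluxes are then proportional to the demands
at fixed concentrations. With nonzero exchange, `U = D delta_c` pins the
inter-cell concentration gaps proportional to the demands while the
saturation terms are not homogeneous, so C is slightly superlinear
(e.g. the measured dual lambda at budget 2C* is 1.98 rather than 2 at
the complementation point `1/K_I = 10, D_X = 10, D_P = 0.1`). Tests
assert the exact law at a non-exchanging optimum and the sandwich
inequality `C(J) >= 2 C(J/2)` generally. For the same reason the forced
split becomes outright infeasible at very low permeabilities: the
required exchange `D max(delta_c)` falls below the demand, which the
package reports as infeasibility rather than a large cost.

## Experiments

**Phase diagrams.** Default grids: 13 log-spaced permeabilities in
[1e-2, 30] plus 0, inhibition strengths `1/K_I in {0.1, 1, 10, 30}`;
acceptance-scale runs use 8x8 grids on [0.01, 30]. Grids are walked in a
snake order with warm-started continuation: each point starts from the
previous optimum, always accompanied by the structured portfolio plus a
few random starts (so branch switches across the transition line are not
missed), with a full multistart fallback when the cost jumps by more
than 20%.

**Regimes.** neutralist (all `|A| <= 1e-3`, no exchange), cheater
(`A_S = 1`, X flows to the second cell, no P returns), complementation
(`A_S = 1`, X flows out, P returns), boundary otherwise; tolerances are
relative to the total demand, and labels are invariant under relabeling
of the cells.

**Extended chain.** The five-intermediate scenario uses `K_eq = 4/3` on
all reversible steps, `1/K_I = 10`, `[S] = 20`, `D = 15` on P and one
chosen intermediate, `1e-3` elsewhere. The optimum splits the chain at
the permeable intermediate, *mostly* cleanly: the producer cell retains
~2% residual expression of the downstream enzymes (its internal product
demand makes a trace of in-house synthesis marginally worthwhile).
`split_point` therefore counts an enzyme as expressed when it exceeds 5%
of its cell's total enzyme — an order of magnitude above the residual
tails and an order below the head enzymes.

**Sensitivity analysis.** The base point sits on the symmetric/split
boundary: `1/K_I = 10`, `D_P = 1`, with `D_X*` found by bisection on the
sign of `C_symmetric - C_split` (geometric midpoints, 1% relative
tolerance). Each of `n` samples multiplies every positive kinetic,
substrate and permeability parameter independently by `exp(u)`,
`u ~ U(-delta, delta)` with default `delta = 0.3` (multiplicative,
preserving positivity), re-optimizes, and records the optimal `A_S`
(restricted to `A_S >= 0`, so `A_S` is effectively the split indicator).
The reported index per parameter is the sample covariance with `A_S`;
the Pearson correlation is reported alongside. Unconverged samples are
excluded and counted.

The deterministic cost-gap curves at the base point fix the true signs:
the symmetric branch cost does not depend on `D_P` at all (no exchange)
while the split branch cost rises with `D_P`, so `D_P` opposes the
asymmetry; `1/K_I`, `[S]` and `D_X` promote it, `K_eq` of the first
reaction weakly promotes it. The `D_P` effect is an order of magnitude
weaker than the `[S]` and `1/K_I` effects, so its covariance estimate
carries a proportionally larger sampling error; per-sample optimization
accuracy matters (the branch decision near the boundary turns on cost
differences of ~1e-2), which is why the sensitivity solves use the full
multistart portfolio rather than a reduced one.

## Permeability module

Descriptors are computed from SMILES with RDKit: average molecular
weight, H-bond donor/acceptor counts, topological polar surface area by
Ertl fragment contributions (N/O contributions; phosphorus itself
contributes zero, its oxygens count), and the Crippen atom-contribution
logP. Structures are taken exactly as given — no automatic
(de)protonation — because fragment TPSA depends on the exact species.
The shipped tryptophan-pathway fixture pins MetaCyc-style charged species
(carboxylates, phosphate dianions; indole and tryptophan neutral); each
record carries a provenance note, including the one internal
inconsistency of the reference descriptor table (the CdRP row's printed
mass matches the neutral monoisotopic species while its TPSA matches the
trianion; the fixture pins the trianion) and the tryptophan TPSA
(computed 79.11 for the neutral form).

Classification uses a declared, editable ruleset
(`data/default_ruleset.yaml`). The one-parameter rule bands TPSA at
60 / 120 / 200 A^2 (H / MH / ML / L); a value exactly on a bound goes to
the less-permeable class and is flagged. The three-parameter rule is an
ordered decision list over TPSA, logP and H-bond donors; its second
clause (`logP > 0.5` and `HBD >= 3` -> ML) captures amphoteric compounds
such as free amino acids, which permeate poorly despite moderate polar
surface area — zwitterion behaviour that no monotone threshold rule on
(TPSA, logP, MW) reproduces. Class rank never increases with TPSA
(property-tested). The calibration target was the seven-compound
tryptophan table (14 labels, all reproduced); the thresholds are config,
not code.

The breaking-point prediction scores interior, non-channeled
intermediates by class rank (3PR by default), breaking ties by lower
TPSA then lower MW. Substrate channeling (e.g. indole inside tryptophan
synthase) is an input flag, never inferred from structure. For the
tryptophan pathway with indole channeled the prediction is anthranilate
(position 2), matching the observed Buchnera/Serratia split; ignoring
channeling, indole and anthranilate tie on class and the tie-break
selects indole.

## Synthetic data

`default_consortium` / `extended_consortium` generate the canonical
parameterizations above; `sample_perturbed_parameters` the multiplicative
perturbations; `synthetic_pathway` fabricates descriptor records (no
structures; records are marked synthetic) with a planted most-permeable
position for round-trip tests of the predictor — designated positions
draw TPSA in [10, 55] (class H) and decoys in [150, 260] (ML/L), so
recovery is exact by construction, which is what the round-trip test is
meant to show. All generators are pure functions of (arguments, seed).

What the generators do *not* emulate about real systems: saturable
(transporter) exchange, intracellular spatial gradients, stochastic
kinetics, correlated parameter perturbations, growth-rate feedback on
demands, and real descriptor noise (synthetic pathways have perfectly
separated classes). Passing tests therefore demonstrate internal
correctness of the model and optimizer under the stated kinetic
assumptions, not quantitative prediction for any particular organism.

## Artifacts and reproducibility

Run configurations are strict-schema YAML (unknown keys rejected).
Results serialize to flat CSV plus full-precision JSON; every artifact
embeds a provenance block (package version, seed, config hash). CSV
files carry the provenance as leading `#` comment lines — a deliberate
deviation from strict RFC-4180 so that provenance lives inside the file;
readers pass `comment='#'`. Re-running with identical config and seed
reproduces byte-identical files.

Problem sizes used by the shipped tests and the acceptance script — 8x8
permeability grids, 24-start multistarts, 200 sensitivity samples, three
extended-chain settings — were chosen to make every run reproducible in
minutes on a single core while keeping the multistart failure rate at
zero across the tested conditions.

## Known limitations

* Local SLSQP with multistart: no global-optimality certificate. The
  structured portfolio covers the symmetric and all single-breakpoint
  split basins; exotic optima outside these patterns would need denser
  random starts.
* The forward-operating restriction excludes reverse-running steps by
  design; it is an optimality argument, not a theorem proved here.
* The sensitivity covariance for weak parameters (notably `D_P`) is
  noise-limited at moderate sample sizes; the deterministic cost-gap
  curves are the sharper instrument for signs.
* logP values are estimator-dependent (Crippen here; other estimators
  give different absolute values); the ruleset is calibrated against
  these computed values and must be recalibrated if the backend changes.
* The competitive-inhibition variant follows the standard competitive
  form; mixed or allosteric mechanisms are out of scope.
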