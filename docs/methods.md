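# Methods

`redoxpoise` models a metabolic network as a system of coupled mass-action
reactions whose thermodynamics are fixed by transformed equilibrium
constants (pH 7.0, ionic strength 0.15 M), and asks how the steady state of
such a system — concentrations, fluxes, and inferred enzyme regulation —
shifts as the cell's redox poise (the boundary ratio of an NADP⁺/NADPH-like
cofactor pair) is swept from strongly oxidative to near-equilibrium
reductive conditions. This note records the model, the numerical choices,
and what the toy-scale validation does and does not establish.

## The network model

A model is a set of metabolites, each with an elemental formula and either
a fixed boundary concentration (set ℐ_f: nutrients and cofactors the
network cannot synthesize) or a variable concentration (set ℐ_v), plus a
set of reactions with signed stoichiometry ν and dimensionless equilibrium
constants K. Fractional stoichiometry and fractional formula subscripts
are allowed throughout; the biomass pseudo-reaction consumes DNA, RNA,
protein and lipid pools in mass ratios (default 1.0 : 2.9 : 44.1 : 8.5,
measured for malate-grown cells, the lipid term closed from a 15% total
fatty-acid mass fraction: x = 0.15·48/0.85 = 8.47).

Structural validation checks elemental balance of every enabled reaction
(residual tolerance 1e-6, hydrogen corrected by a per-reaction declared
proton exchange, because transformed thermodynamics absorb explicit H⁺
into K), numerical rank of the stoichiometric matrix (singular values
below 1e-9·σ_max treated as zero), and steady-state feasibility (the
variable-row submatrix must have a nontrivial null space).

Free-energy offsets on reactions represent driving forces not captured by
K itself; the transmembrane proton gradient contributes
−n_H⁺·RT·ln(fold) to the ATP-synthase ΔG°′ (default 4 protons, 10-fold;
a stronger-gradient scenario is expressed as (4, 50)).

## Thermodynamic odds and the redox parameterization

The central quantity is the thermodynamic odds K/Q of a reaction (Q the
mass-action reaction quotient): 1 at equilibrium, >1 when the forward
direction is favored. All logs are natural. Redox conditions are
parameterized by the odds of H₂ oxidation in the reference reaction
NADP⁺ + H₂ ⇌ NADPH with ΔG° = −35.0 kJ/mol at T = 298.15 K and the
standard-hydrogen-electrode reference concentration [H₂] = 1 M (a fixed
convention, not a parameter), so that

    [NADP⁺]/[NADPH] = odds · exp(ΔG°/RT).

An odds of 1e10 maps to a ratio of 7377.8; 1e4 to ≈7.4e-3, near the
textbook physiological poise. The inverse map is exact, and requested
versus actually-used odds are carried separately on each condition so
that convergence-rescue perturbations of the boundary ratio remain
auditable.

## Maximum-entropy steady state

Given a steady-state flux pattern ξ̇ (a null-space vector of the
variable rows of S, scaled so carbon-source uptake equals 1000
molecules/s; the minimum-norm combination is used when the nullity
exceeds one), the most likely concentrations satisfy the
stationary-action conditions

    sign(ξ̇_j) · log(K_j/Q_j) = λ   for every ξ̇_j ≠ 0,
    reactions with ξ̇_j = 0 sit at equilibrium,

i.e. every flux-carrying reaction dissipates the same free energy per
unit advancement, with λ the shared Lagrange multiplier. Because log Q
is linear in log concentrations, these conditions are a linear system
solved by least squares jointly in (x, λ); metabolites touched only by
zero-flux reactions are then placed at equilibrium in a second
least-squares stage, and anything constrained by neither is reported as
undetermined at 1 M. The least-squares system weights all flux-carrying
reactions equally (weighting by |flux| changes nothing on uniform-flux
pathways and was not adopted for lack of a principled weighting).
A per-species correction for reactions that change particle count
(a chemical-potential factor e^{βμ_B·Σγ}) is disabled by default — the
control law below is defined for particle-conserving reactions — and can
be enabled as a configured constant.

Two independent cross-checks guard the solver. First, an exhaustive grid
over log concentrations of small chains must land on the same state
(selected as the grid point minimizing the spread of per-reaction log
odds — a brute-force route to the same stationarity conditions; note
that the total entropy production Σ_j ξ̇_j log(K_j/Q_j) itself is exactly
constant over concentrations at a fixed steady-state flux, its gradient
being −S·ξ̇ = 0, so it cannot serve as a grid objective). Second, rate
parameters are back-computed from the state (k₊/k₋ pinned to K, the
per-reaction timescale fixed by reproducing the steady flux, unit
timescale k₋ = 1 for zero-flux reactions) and the mass-action ODEs are
integrated with fixed species clamped: the maxent state must be a fixed
point to within 1e-6 relative drift over a thousand characteristic
times.

## Pathway-controlled optimization (PCO)

Unregulated mass-action kinetics drive some metabolite pools to
physically implausible concentrations. Regulation is modeled by a
per-reaction activity coefficient α ∈ [0, 1] scaling the reaction's
odds difference, and the regulated steady state is the solution of

    max  Σ_{g ∈ 𝒢} α_g (K_g/Q_g − Q_g/K_g)       (𝒢 = growth reactions)
    s.t. steady state of every variable metabolite,
         0 ≤ n_i ≤ n_max,  fixed species at their boundary values,
         0 ≤ α_j ≤ 1.

The flux entering the steady-state constraint is the activity-scaled
difference of forward and reverse transition probabilities,
ξ_j = α_j·2 sinh(log(K_j/Q_j)/Mb). The conditioning hyperparameter Mb
(default 1000) scales the reaction free energies inside the solver so
the exponentials remain in a numerically benign near-linear regime; the
solver's internal objective applies the same Mb conditioning as the flux
law — with mismatched scalings the optimizer exploits the mismatch by
down-regulating the growth reaction while inflating its odds, a spurious
optimum — and the reported objective is the unscaled sum above evaluated
at the optimum. The default log-concentration lower bound is −300
(hyperparameter `var_m_lbound`), the default concentration cap 1 M per
variable metabolite unless the metabolite declares its own.

The problem is solved over (log-concentrations, α) with scipy's
`trust-constr` (a trust-region interior method) with analytic gradients
and constraint Jacobians, initialized from the maxent state with α = 1.
Feasibility of a reported solution (steady-state residual, bound
violations) is asserted post hoc, independently of the solver's own
status. A tiny quadratic regularization (1e-6·Σ(1−α)²) breaks ties among
equally optimal activity patterns toward minimal regulation. Identical
inputs and seed give identical iterates; the optional multistart
perturbs only the initial point with the seeded generator.

On chain-structured pathways the solution is provable: the pathway's
total driving force A = Σ_j log(K_j/Q_j) telescopes to a constant fixed
by the boundary, the optimum splits it equally across steps with all
α = 1 (exactly the maxent state) when no bound is active, and pins the
violating metabolite at its cap with the upstream activity reduced by
the ratio of sinh terms when one is. Both regimes are verified against
an exhaustive α-grid oracle (α on a 0.01 grid, the inner steady state
found by bisection).

Non-convergence is handled the way the sweep protocol prescribes: the
NADP⁺/NADPH boundary ratio is perturbed by alternating ±2.5% steps (the
magnitude of the published 7.38e-4 → 7.57e-4 adjustment) and the
requested and actual odds are both recorded. Exhausted retries return a
failure object carrying the best iterate; failed conditions keep their
slot in sweep outputs.

## The redox sweep and its readouts

For each target odds the boundary ratio is set, PCO run, and the
readouts collected: the growth objective and growth flux, marker-
reaction fluxes (a named config section, since reaction ids differ
between model files), concentration ratios of declared redox pairs
(free, unbound species — deliberately not whole-cell assay values), and
the net exchange of every boundary metabolite (S_fixed·ξ̇, negative =
consumption), normalized to a carbon uptake of 1000. Fluxes are
normalized by |uptake| so directions are preserved when the net
carbon-source exchange reverses under strongly reductive boundaries.
Elemental conservation of the boundary exchange (formula-weighted rates
summing to zero per element) is asserted on every run.

## Biomass composition bookkeeping

The overall growth reaction is the thresholded boundary exchange
(species below 1/100 of the carbon-source rate dropped; declared
internal cofactors dropped except a phosphate keep-list), optionally
rescaled to the 10-substrate-unit convention of the worked examples.
Redundant redox carriers are merged by adding the right multiple of a
declared substitution reaction (e.g. NADP⁺ → NAD⁺ + Pi) and cancelling
like terms, with the substitution's elemental neutrality checked when
formulas are available.

The biomass formula C₄H_uO_fN_z is then solved by replacing the reduced
carrier by H₂ (and the oxidized partner by a variable amount of water),
fixing the oxygen subscript f from elemental analysis (2.04 for
malate-grown, 1.57 for acetate-grown biomass), and balancing C → N → O
→ H in closed form; all four balances hold exactly by construction and
a negative solved coefficient raises an error naming the failed
balance. The carbon oxidation state is Z_C = (−n_H + 2n_O + 3n_N)/n_C,
with phosphorus and sulfur excluded by convention.

Two published-table discrepancies are handled by reporting the balanced
values rather than matching print: the ~neutral malate cell-cycle row
(balanced: 2.55 H₂, 2.96 H₂O; printed: 2.63, 3.04 — the printed row
does not close the element balances with the stated biomass formula),
and the average-amino-acid Z_C (the caption formula gives −0.10 with
sulfur ignored; the printed 0.05 implies an unspecified sulfur
treatment, so that entry is not asserted).

## Synthetic data: what the toys emulate, and what they do not

The generators produce exactly balanced toy networks: isomerization
chains (one shared formula, fixed 1 M ends, Keq either pinned or
sampled log-uniformly over [1e-3, 1e3] with a seeded generator — the
decade range covering the regimes where control activates), and a
12-species "dissipative cell" with a substrate (C₂H₄O₂ at 0.01 M), CO₂,
NH₃, water, a fixed carrier pair (reduced species 1e-3 M, oxidized set
by the swept ratio), a biomass-monomer sink, a three-step reductive
growth pathway, a boundary-only oxidation branch, and a dead-end
isomerization. The construction makes three study findings provable at
toy scale: the optimal growth objective is monotone in the boundary
redox poise (the pathway driving force is A₀ − log ratio), the net CO₂
exchange flips sign between reductive and oxidative conditions (the
oxidation branch couples only boundary species), and the dead-end
carboxylation analogue carries exactly zero flux.

What the toys deliberately lack: network scale (hundreds of reactions),
cycles sharing conserved moieties (ATP/ADP, CoA pools), electron-
transport stoichiometry, and competing assimilation routes. Passing the
toy suite therefore validates the solver contracts and the qualitative
redox trends, not the study's genome-scale flux magnitudes; those
depend on an unpublished non-convex reformulation and a curated model
distributed only as supplementary spreadsheets, and are treated as soft
references. Problem sizes used in the shipped tests (chains of 2–4
steps, the 12-species cell, four-condition sweeps) were chosen as the
smallest instances on which each property is non-trivial.

## Known limitations

- Global optimality of PCO solutions is not claimed; the problem is
  non-convex and only KKT points with post-hoc feasibility are reported.
- The activity law is applied uniformly, including to the few reactions
  that change particle count, for which no separate control law exists.
- Rate-parameter back-computation fixes one timescale per reaction; only
  odds and directions, not absolute rates, are identified.
- No SBML/BioPAX I/O, no free-energy estimation (K is consumed as
  input), no ensemble sampling over rate parameters, and no uncertainty
  propagation over ΔG°.
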