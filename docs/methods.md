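# Methods

## Scope and model

fluxkit works on genome-scale metabolic models (GSMs) in the standard
constraint-based framework.  The feasible flux space for a condition *k* is

    Ω_k = { v ∈ ℝ^J : Σ_j S_ij v_j = 0 ∀ i,  l_jk ≤ v_jk ≤ u_jk ∀ j }

with S the stoichiometric matrix (metabolites × reactions), fluxes in
mmol/gCDW/h and growth in 1/h.  Exchange reactions follow the FBC
convention (one extracellular species, negative flux = uptake, `EX_`
prefix).  Conditions modify bounds only, never S — with one exception: the
growth-associated maintenance (GAM) is a stoichiometric coefficient on the
ATP-hydrolysis term (atp + h2o → adp + pi + h) inside the active biomass
reaction, so installing a fitted GAM rewrites those five coefficients.
Non-growth maintenance (NGAM) is the lower bound of the dedicated ATP
hydrolysis pseudo-reaction (`ATPM`).

Measured extracellular fluxes (mean μ ± sd σ, typically from triplicate
fermentations) constrain the model as l = μ − σ, u = μ + σ, an interval
with better than 90% coverage for normally distributed triplicates.  Gene
deletions act through the boolean gene-protein-reaction (GPR) rules:
a reaction whose GPR evaluates false with the deleted genes set to false
gets both bounds zeroed.  Reactions without a gene association are never
disabled by gene deletions.

## Solvers and numerical choices

* **FBA** (maximise c·v over Ω_k): HiGHS LP through
  `scipy.optimize.linprog`, feasibility/optimality tolerances 1e-9.  Only
  the objective *value* is contractual; degenerate optimal flux vectors
  are solver-dependent and downstream code never relies on them.
* **Quadratic pFBA** (minimise Σ v² over Ω_k): OSQP with
  eps_abs = eps_rel = 1e-10 and solution polishing.  The objective is
  strictly convex, so the minimiser is unique; repeat solves agree to
  better than 1e-6 per flux.  Deliberately, *no* growth-maximisation
  pre-step is performed — the measured bounds are expected to pin the
  physiological state, and the quadratic program is the entire method.
  A test verifies the returned point against an independent KKT
  certificate (existence of stationarity multipliers with correct signs),
  which for a convex program proves global optimality.
* **FVA**: per-reaction min/max LP over Ω_k.  **Loopless FVA** adds the
  standard mixed-integer loop-law construction on internal reactions
  (binary direction variable a_j, potential variable G_j with
  G_j ∈ [−M, −1] when a_j = 1 forces v_j ≥ 0 and G_j ∈ [1, M] when
  a_j = 0 forces v_j ≤ 0, plus k·G = 0 for every basis vector k of the
  internal null space), solved with HiGHS MILP via `scipy.optimize.milp`.
  Big-M is 1000, matching the global flux bound; exchanges and biomass
  pseudo-reactions are exempt.  A loopless subproblem that exceeds its
  time limit (default 30 s) falls back to the plain LP bound and is
  flagged `relaxed`.
* Default bounds are ±1000 mmol/gCDW/h where a model omits explicit ones.
  Reported-solution checks (mass balance, bound containment, FVA nesting)
  use 1e-6.
* **Blocked reactions** are computed with every exchange opened to ±1000
  (the most permissive scenario, hence the smallest blocked set); a
  reaction is blocked iff its FVA interval is {0} within 1e-6.  The set is
  invariant to the exact exchange bound magnitude.

## Maintenance training

For each training condition the model is bounded with the measured
exchange fluxes and growth rate, GAM is zeroed inside biomass and the NGAM
bound dropped to zero, and the ATP-hydrolysis flux is maximised.  Zeroing
the shipped maintenance terms routes *all* spare ATP through the
hydrolysis reaction, so the regression of max-ATP (y) on measured growth
(x) absorbs growth-proportional ATP into the slope (GAM) and the constant
demand into the intercept (NGAM).  The alternative (keeping the shipped
GAM) is exposed as `zero_gam=False`.  The fit is ordinary unweighted least
squares: measurement uncertainties enter through the flux bounds, not as
regression weights.  Outliers are caller-designated flags — no automatic
criterion is applied.  A negative fitted NGAM is physically suspect and is
returned with a warning status rather than rejected.  Note that because
the training LP maximises ATP over the ±σ box, the fitted intercept
carries a small upward bias of order (ATP yield)·σ; the slope is
unaffected.

## Fold-change omics integration

The protocol compares gene-level log2 fold changes (case vs control) with
simulated flux fold changes:

1. both conditions are bounded by their measured fluxes; the mutant
   additionally receives its gene deletions;
2. quadratic pFBA and (by default loopless) FVA are run in both states;
3. fluxes are normalised by the substrate uptake rate, floored at
   ε = 1e-4, and compared as log2 ratios; the FVA interval is summarised
   by its midpoint (the *FVA centre*), a heuristic shift indicator that
   need not itself be a feasible flux;
4. gene fold changes are mapped to reactions as the plain mean over GPR
   genes with nonzero fold change, ignoring AND/OR structure;
5. a reaction is *consistent* when its measured fold change strictly
   shares a sign with at least one simulated fold change;
6. Pearson correlations between measured and simulated fold changes are
   reported over the consistent set only.

Three edge conventions are worth spelling out.  (i) *floor(0) := +ε*: the
flooring function's "otherwise" branch would leave 0 unchanged and make
log2 undefined; +ε is the continuous extension of the positive branch and
makes "zero in both conditions" yield a fold change of exactly 0.  Records
touched by this are flagged `floored_zero`.  (ii) A *sign flip* between
conditions has no defined log ratio; such records carry the magnitude
log2(|a|/|b|), are flagged `sign_reversal`, and are excluded from the
Pearson correlations.  In practice the protocol normalises secretion
fluxes, which are non-negative, so these flags are rare.  (iii) The
normalising uptake is each method's own simulated value for the designated
substrate exchange (pFBA flux, FVA centre); since measured bounds pin the
uptake to μ ± σ this choice is numerically almost identical to using the
measured mean, but keeps each fold change internally consistent.
Statistical-significance columns in gene tables are accepted but unused:
the mapping criterion is FC ≠ 0, nothing more.

## Phenotype screens

Mutant growth percentages are 100·(mutant max growth)/(wild-type max
growth) under the same condition; a percentage below 20% is called lethal
(threshold exposed).  Supplement rescues open the supplement's exchange
uptake (unbounded by default, i.e. 1000 mmol/gCDW/h — published rescue
percentages above 100% imply effectively unconstrained supplementation)
and remain normalised to the *unsupplemented* wild type.  The
single-reaction-deletion scan zeroes every not-already-disabled reaction
on top of a base genotype and re-maximises growth, recording per-reaction
infeasibility as zero growth; uptake is left free within the medium caps
rather than pinned to measured values.

## Synthetic fixtures: what they emulate and what they do not

The **chain toy** (substrate → ATP-generating chain → parallel routes →
secretion, plus ATPM and three biomass variants) exercises LP/QP/MILP
contracts and maintenance training: its ATP yield per substrate (default
4) and biomass ATP coefficient (default 12) make growth require overflow
catabolism, as in the real organism.  The **redox core** miniaturises the
*C. thermocellum* pyruvate/ferredoxin node: POR vs PFL at pyruvate,
ethanol (2 NADH/acetyl-CoA) vs acetate (+ATP) at acetyl-CoA, hydrogenases
ECH (ferredoxin), BIF (bifurcating, ferredoxin+NADH) and an NADPH-linked
H2ASE — the latter two requiring a shared maturase gene so that deleting
it silences both, mimicking *hydG* genotypes — plus RNF and NFN
oxidoreductases and a ketoisovalerate → isobutanol NADPH sink that serves
as the medium-supplement rescue.  Stoichiometries are proton/water-free
simplifications; hand-solved LP optima on this network (wild type 38/13
1/h at uptake 10; hydrogenase double mutant 28/12.45; the additional
alcohol-dehydrogenase deletion lethal through electron imbalance;
ketoisovalerate restoring the full wild-type optimum) are frozen as test
oracles.

The maintenance generator perturbs the ATP demand gam·μ + ngam with
seeded Gaussian noise and derives the consistent uptake through the ATP
yield.  The omics generator pins each strain to measured uptake and 95%
of its maximum growth, computes the true pFBA state, and plants gene fold
changes (exact values or fixed magnitudes) on shifted branches whose
genes are exclusive to one reaction, so the planted reaction fold change
maps back exactly; the returned expected set is what the protocol must
recover at zero noise.  Default generator settings (uptake 10 mmol/gCDW/h,
GAM 12, NGAM 2, eight growth rates 0.05–0.4 1/h, training noise sd 0.3)
are fixed study conditions, not tuning knobs.

Fixtures encode topology and statistical structure only: they do not
reproduce the organism's quantitative fluxes, compartmental proton
bookkeeping, thermodynamic driving forces, or the size and degeneracy of a
real genome-scale network.  Passing fixture tests therefore demonstrates
correctness of the algorithms and bookkeeping, not predictive accuracy on
real fermentation data; the latter requires the deposited genome-scale
model and measured tables, consumed through the same interfaces when
available (see `tests/test_deposited_model.py`).

## Known limitations

* Quadratic pFBA accuracy is bounded by OSQP's polished solution
  (~1e-8); extremely ill-conditioned models may need tighter settings.
* The loopless MILP enumerates the internal null space densely; it is
  intended for curated models of a few thousand reactions at most, and
  per-reaction time limits degrade gracefully to LP bounds.
* Proton/water balance correction only repairs residuals confined to
  H, O and charge; anything else is reported as uncorrectable.
* The FVA centre is a deliberate heuristic: it indicates range shifts and
  can miss permutations of fluxes inside unchanged ranges.
* Growth-condition classes for validation are derived from reactor mode
  and carbon source only; more granular parameter classes require caller
  bookkeeping.
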