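# Methods

## Model and assumptions

`tmeflux` performs constraint-based flux estimation on a genome-scale
metabolic model (GEM): a stoichiometric matrix **S** (M metabolites × N
reactions, negative coefficients consume, positive produce), per-reaction
reversibility, gene–protein–reaction (GPR) rules, a set of exchange
(boundary) reactions each moving one extracellular metabolite, and a
biomass pseudo-reaction encoding the composition and demand of cell growth.
The core assumptions are:

1. **Steady state.** Metabolite concentrations are constant: `S v = 0`.
2. **Expression caps activity.** mRNA level is treated as a proxy for the
   maximum amount of enzyme available, so GPR-derived activity scores bound
   the flux a reaction can carry. No kinetic constants or binding
   affinities are used — they cannot be estimated robustly at genome scale.
3. **Growth objective.** The sample's cells are assumed to maximise the
   generic biomass reaction (appropriate for proliferating tumor tissue);
   in the community model the *total community* biomass is maximised,
   reflecting strong metabolic interdependence of cell groups in a TME.
4. **Binary nutrient environment.** The medium is a presence/absence list;
   concentrations and uptake-rate caps are out of scope.

All fluxes are relative, dimensionless scores (bounds live on [−1, 1]):
only comparisons across samples, reactions, or groups are meaningful, not
absolute rates in mmol/gDW/h.

## Reaction activity scores (MRAS)

For each enzyme-associated reaction, the GPR tree is evaluated bottom-up on
leaf values `expr(gene) / w(gene)`, with OR = sum (isoenzymes act
additively) and AND = min (the least-expressed subunit of a complex is rate
limiting). `w` counts the distinct reactions a gene appears in, once per
reaction regardless of multiplicity within a rule, over all rule-bearing
reactions of the loaded model; this splits a promiscuous enzyme's capacity
across its reactions. Design choices where the convention was genuinely
open:

- **Operator precedence**: AND binds tighter than OR (standard boolean
  convention; curated GEM rules are typically fully parenthesised anyway).
- **Missing genes** (in a rule but not measured) contribute expression 0 by
  default — conservative, since an unmeasured complex subunit then zeroes
  the complex. A `missing_gene="drop"` switch removes such leaves instead.
- **Duplicate gene rows** in the expression matrix are summed before
  evaluation, making results order-independent.

Note that OR-of-AND semantics are *not* preserved by boolean rewriting:
`min(a, b+c) ≠ min(a,b) + min(a,c)`, so rules are evaluated on the tree as
written, and the test-suite's independent evaluator is only applied to
rules already in flat isoenzyme-of-complex form.

## Flux bounds and media

Per sample, enzyme-associated reactions get `ub = MRAS / max(MRAS over
reactions)`, so exactly one reaction per sample sits at the bound ceiling 1
and bounds are invariant to rescaling a sample's expression by any positive
constant (library-size invariance, inherited by the fluxes). Reversible
reactions get `lb = −ub`; reactions without gene association get (0, 1) or
(−1, 1).

Applying a medium sets `lb = 0` on exchange reactions whose metabolite is
absent (secretion-only) and leaves present metabolites at their existing
range; it never widens a bound and never touches non-exchange reactions.
Irreversible exchange reactions keep `lb = 0` even for medium metabolites —
they cannot be forced to take up. Bundled profiles: `cell_line` (44
metabolites, transcribed from the Ham's F-12 composition plus serum-derived
essentials) and `human_blood` (64 metabolites, from the human plasma-like
medium composition). Metabolite-to-exchange matching is by extracellular
metabolite identifier, case-insensitive; unmatched entries warn by default
and can be escalated to errors.

## The quadratic program

```
min ½ vᵀv − a cᵀv    s.t.  S v = 0,   lb ≤ v ≤ ub
```

The strictly convex objective folds parsimonious FBA into one solve: among
high-biomass flux states the minimum-norm one is selected, and the solution
is unique — no flux-variability post-processing is needed. `a = 10,000`
puts the linear biomass reward at the same order of magnitude as the summed
quadratic penalty of ~10⁴ reactions with |v| ≤ 1; biomass deviates from its
constrained maximum by at most O(‖v‖²/a). The zero vector is always
feasible (all boxes contain 0), so the problem never becomes infeasible,
the optimal objective is ≤ 0, and biomass flux is ≥ 0.

Numerical choices: OSQP (sparse ADMM) with `eps_abs = eps_rel = 1e-9`,
solution polishing on, iteration cap 200,000; `S v = 0` is passed as hard
equality rows, with a post-solve check that `‖Sv‖∞ ≤ 1e-6` (raising
otherwise). The tight tolerances plus polishing give agreement with a dense
KKT active-set reference to ~1e-10 per component on small networks. Each
sample is solved independently (cold start) for determinism.

## Community model

For n cell groups with fractions `p_i > 0, Σ p_i = 1`, the merged system
has block structure: n copies of (S, bounds) on the diagonal; each group's
exchange columns rewired into coupling reactions `m_e(group i) ↔ rm` by
mirroring the exchange coefficient onto a reservoir metabolite row (one
`rm` per exchange metabolite, shared by all groups); and reservoir exchange
columns `rm ↔ ∅` opening the system. Dimensions:
`(n·M + M_ex) × (n·N + M_ex)`.

The QP becomes `min ½ vᵀPv − a cᵀPv  s.t.  SPv = 0` with
`P = diag(p_1 … p_1, …, p_n … p_n, 1 … 1)` and `c` indicating every group's
biomass reaction. Group variables are *per-cell* fluxes; the reservoir rows
of `SPv = 0` force `shared exchange flux = Σ_i p_i · coupling flux_i` for
every exchange metabolite, which is the contribution-accounting identity
used downstream. Bound conventions:

- Group-block reactions, including couplings, use the group's own
  expression-derived bounds (the medium is *not* applied at group level, so
  groups may consume each other's secretions).
- Reservoir exchanges: `ub = 1`; `lb = −1` if the metabolite is in the
  medium, else 0.
- MRAS normalisation is per group column within each bootstrap replicate —
  the bulk procedure applied to each group's mean expression vector.

A single group at `p = 1` reproduces the bulk solution's exchange fluxes
whenever the optimum is bottleneck-determined. Under degeneracy (several
flux routings achieving the same biomass) the community formulation's extra
quadratic penalty on reservoir-exchange variables can select a different
point of the optimal face; this is a property of the model family, not a
solver artifact, and the equivalence checks therefore use backbone-only
networks whose optimum is unique.

Group fractions should come from experiment or deconvolution; if absent,
observed label proportions are used with a warning (dissociation bias can
distort them). Groups under 5 cells trigger a warning — group-mean
expression is noisy there — but are not excluded automatically.

Stratified bootstrap: each replicate redraws cells with replacement within
each group, preserving exact group sizes, then the whole
means → MRAS → bounds → community-QP chain runs per replicate (default 100
replicates). Reported per-group fluxes are per-cell averages; shared
exchange fluxes are community totals.

## Downstream readouts

- **Direction calls**: uptake (flux < −ε), excrete (> ε), no-flux
  (|flux| ≤ ε), with ε = 1e-8 on the normalised scale — a conceptual zero
  is numerically untenable after QP. Direction accuracy is the fraction of
  exact categorical matches.
- **Interaction modes** per exchange metabolite: all groups uptake →
  competition; all secrete → release; mixed signs → cooperation. No-flux
  groups are ignored; all-no-flux is "unclassified" (the all-zero pattern
  is not defined by the classification and is reported rather than forced).
- **PCCS**: |tumor per-cell uptake| / |effector per-cell uptake|, > 1 when
  the tumor out-consumes the effector per cell; undefined (error) when the
  effector flux is within ε of zero.
- **Random-medium significance**: N same-sized media are drawn uniformly
  without replacement from the exchange metabolites; the user's statistic
  (e.g. correlation with measured fluxes, or direction accuracy) is
  recomputed per draw, and `p = #(sim ≥ obs)/N` — plain counting with no +1
  correction, so p can be exactly 0; a `(k+1)/(N+1)` variant is available.
  Failed simulations are excluded with N reduced and recorded.

## Synthetic data

The toy-GEM generator emits a guaranteed backbone — reversible nutrient
exchange → GPR-bearing unit conversions → biomass sink — plus random
decorations: extra exchanges and unit conversions (coefficients ±1, so mass
enters only through exchanges), random reversibility, and random GPR rules
over a shared gene pool (creating promiscuity). This guarantees biomass is
achievable under a full medium and provably zero under an empty one.
Expression generators produce log-normal, TPM-like values for the gene
universe plus decoys; the single-cell generator adds per-cell
multiplicative noise and independent Bernoulli dropout around group
profiles.

What this does *not* emulate: realistic transcriptome covariance, counts
sparsity beyond Bernoulli dropout, genome-scale network size, or curated
GPR complexity. Passing tests therefore demonstrate algorithmic
correctness — solver exactness, invariances, conservation identities,
counting contracts — not predictive accuracy on real tissue, which requires
a real GEM (e.g. loaded from SBML) and measured fluxes.

Test and acceptance runs use networks of ~5–15 reactions and bootstrap
counts of 10–100; these sizes make the exhaustive KKT oracle exact and the
full suite fast while exercising every code path.

## Known limitations

- Binary medium only; no nutrient concentrations or uptake caps.
- Generic biomass objective; no cancer-specific biomass formulation.
- Single-cell fluxes are resolved at group level, not per cell — cell-wise
  scores from zero-inflated data would be dominated by dropout.
- SBML is read-only; writing uses the tabular dialect.
- Bundled media are name lists; mapping them onto a particular GEM's
  metabolite identifiers may require a synonym file for that model.
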