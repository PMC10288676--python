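# Methods

## Scope and model classes

`commsteady` computes metabolically stationary states of communities of
constraint-based metabolic networks under four combinations of environment
and decision making:

* **CA** — chemostat, rational agents: each species maximizes its own growth
  rate given the extracellular concentrations `C`, which enter only through
  concentration-dependent capacity bounds `b(C)` (uptake kinetics). Steady
  state couples the agents through the compound balances
  `D (C_in − C) = Σ_i T_i ν_i X_i` and the D-growth condition
  `X_i (D − ν_μ,i) = 0`.
* **CC** — chemostat, rational community: one decision maker jointly chooses
  all fluxes *and* the extracellular concentrations to maximize total
  biomass production `Σ_i ν_μ,i X_i` (or, optionally, the sum of growth
  rates over the present species), subject to the same balances. The
  abundances `X` are never optimization variables: if different abundance
  vectors favor different species, the model does not presume to know which
  the community would pick.
* **BA / BC** — steady-state batch: concentrations are not represented;
  relative abundances `x` sum to one, all present species grow at one rate
  `μ*`, and community-level uptake bounds `u` cap the abundance-weighted
  exchange fluxes. BA (agents in batch) is assembled for completeness; a
  community steady state then requires unrelated species to share their
  maximal growth rate exactly, which essentially never holds, so BA admits
  little beyond single-species solutions.

All quantities are treated as consistent arbitrary units; nothing is
converted.

## KKT reformulation

The inner optimizations are linear programs in their decision variables, so
KKT conditions are necessary *and* sufficient. Each model is assembled as a
single polynomial system in a flat variable vector
(`ν`, `C`|`x`+`μ*`, `X`, `λ₁`, `λ₂`): outer balances, growth pinning,
intracellular steady state, KKT stationarity, and complementary slackness in
the multiplicative form `λ₁ ⊙ q = 0` with `q` the slack of the paired
inequality. Piecewise-linear concave bounds are expanded piece-by-piece into
separate inequality rows, each carrying its own multiplier; the stationarity
term `−db/dC` then emerges automatically as the active piece's gradient
(subgradient selection at kinks is implicit in which piece's multiplier is
nonzero). Every equation is polynomial of degree ≤ 3 (degree 3 only in the
batch complementarity products `λ·x·ν`), which gives exact, cheap Jacobians
shared by all solver stages.

Support indicators in the sum-of-growth objective (`δ(X_i > 0)`) are
operationalized as `X_i > 1e-9` and frozen per branch/candidate, keeping the
inner problem linear per branch.

## Certification

A candidate is accepted only if

1. its maximal constraint violation over the *full* system is below 1e-8
   (equalities as absolute values, inequalities as positive parts), and
2. re-solving the inner LP at the candidate's outer variables (per species
   at fixed `C` for CA/BA; jointly over `(ν, C)` at fixed `X` for CC; over
   `ν` at fixed `x` for BC) leaves an optimality gap below 1e-6.

The second check is independent of any multipliers, so the pipeline can
never certify itself through a bad dual solution.

## Active-set oracle (small models)

Every inequality is either active (slack zero, multiplier free) or inactive
(multiplier zero), and every species either absent or growth-pinned;
enumerating all `2^(n_ineq + n_species)` branches therefore covers every
steady-state branch — the numerical replacement for solving the small
systems symbolically. Per branch:

1. **Species elimination.** The linear equations of each present species
   (steady state, growth pinning, tight capacity rows) are solved once by
   SVD, yielding an affine parametrization of its fluxes in the shared tail
   variables (`C`, resp. `μ*`) plus induced linear constraints on that tail.
   Results are cached per (species, tight-set), and tight-sets inducing the
   same solution family are solved only once.
2. **Balance block.** The remaining bilinear equations (compound balances in
   `ν·X`; culture rows and `Σx=1` in batch) are solved over the affine
   family by a damped Gauss-Newton iteration from one deterministic start
   plus seeded random starts (extra starts only for underdetermined
   families, which are genuine solution continua, and for failed
   deterministic starts).
3. **KKT pinning (stage 3).** Some isolated steady states sit strictly
   inside a balance-underdetermined family and are pinned only by the
   stationarity rows (this happens in CC, where `−db/dC` couples the
   multipliers to `C`). When no sampled root of such a family passes the
   full residual check, Newton is re-run on the branch's complete KKT
   system with the multipliers as unknowns.
4. **Assembly.** Absent species receive their growth-maximal (CA/BA) or a
   feasible (CC/BC) flux vector from an LP solve; multipliers are recovered
   by least squares on the stationarity rows with non-negativity on tight
   rows (projected NNLS); the candidate then faces the certification above.

For continuum families the deterministic representative is canonicalized by
sliding along the root manifold to the point nearest the neutral reference
(equal abundances), so e.g. species-exchange-symmetric models report the
symmetric member of a solution segment; further members are reported as
sampled representatives. The oracle characterizes such bands by isolated
representatives only — mapping a band densely is the grid stage's job.

Branch spaces beyond the pattern budget (default `2^22`) raise an explicit
error directing users to the MILP stage.

## Grid MILP stage (chemostat models of any size)

Fixing `X` to a grid point makes everything linear except complementary
slackness, which is linearized with binaries `Δ` and a big-M constant:

```
0 ≤ λ₁ ≤ Ω Δ        −Ω (1 − Δ) ≤ q ≤ 0
```

The equalities containing the fixed `X` (compound balances, D-growth) may be
infeasible off the steady-state manifold, so each receives a pair of
non-negative slacks; the MILP (HiGHS via `scipy.optimize.milp`) minimizes
their L1 sum. Near-zero minimal slack marks steady-state candidates; the
candidate's true residual (slacks removed) and its max-violation norm are
both recorded.

`Ω` defaults to `10 × max(max C_in, max constant bound piece, D·n_C·max
C_in, 1)` with a floor of 10; any incumbent with a multiplier or slack above
`0.99 Ω` triggers an automatic re-solve at `10 Ω`. The per-point time limit
defaults to 60 s and is configurable; points that hit it keep their
incumbent and are flagged, since time-limited points show up as
irregularities in residual maps. Ties among alternate MILP optima are left
to the solver; downstream deduplication absorbs the multiplicity.

## Refinement and acceptance

Each grid candidate seeds a Levenberg-Marquardt minimization
(`scipy.optimize.least_squares`) of the squared residual vector — all
equalities, hinge terms `max(0, violation)` for the inequalities, and the
complementarity products — with **all** variables free, abundances included,
so candidates migrate off the grid onto the solution manifold. Hinges are
the natural least-squares embedding of the inequalities; the complementarity
products are kept in the refined residual. Starts without multipliers (e.g.
hand-entered flux tables) first receive least-squares-initialized
multipliers, without which LM reliably stalls in a complementarity local
minimum. Refinement never returns a candidate with a larger sum of squares
than its start; local minima above the acceptance threshold are simply
dropped, which is the documented failure mode of gradient refinement.
Deduplication merges candidates within 1e-6 (∞-norm) in concatenated
abundance/concentration space — 100× the acceptance threshold, separating
numerically identical roots without merging neighboring members of a
solution band on any reasonably spaced grid — keeping the lowest-residual
representative.

## Fixtures and what the synthetic data does (not) show

* `pd_network()` — the two-species metabolic prisoner's dilemma: shared
  substrate S, growth consuming one unit each of intracellular A and B,
  species 1 converting S→A at yield 1/2 and S→B at yield 1 (species 2
  mirrored), uptake caps equal to the matching concentration. The yields are
  fixed by requiring joint consistency with the steady states of all
  four reference scenarios. The batch variant drops the (concentration-dependent) uptake caps
  and leaves limitation to the culture bounds `u`.
* `coexistence_network(a1, b1, a2, b2)` — two species needing both supplied
  compounds in mirrored ratios, uptake-only transports (crossfeeding
  structurally impossible); kinetic caps `ν_t ≤ 2C` (chemostat) or constant
  caps of 2 (batch). The published figure does not print the stoichiometric
  coefficients; the defaults (2,1)/(1,2) realize the stated asymmetry and
  are validated qualitatively (regime sequence washout → single-strain rise
  → coexistence window → fall; batch single-strain relative concentrations
  identically one).
* `auxotroph_pair_toy()` — a deliberately small, hand-built synthetic
  stand-in for an amino-acid-auxotrophic syntrophic pair: each strain lacks
  the synthesis route for one required compound and can overproduce the
  partner's from an energy source supplied in excess (inflow: energy 10,
  each amino acid 2, D = 0.5 — chosen so that single strains are
  amino-acid-limited well away from washout). It reproduces the *mechanism*
  — agent-model coexistence bands from wasteful-but-optimal energy
  allocation, versus a small isolated community-model solution set — but
  none of the genome-scale numbers; passing tests on it say nothing about
  any particular organism's stoichiometry.
* `random_community(seed, ...)` — seeded property-test communities with a
  guaranteed uptake→conversion→growth pathway per species.
* `syntrophic_pair(sbml_path, params)` — the genome-scale route: builds an
  alanine/glutamine auxotroph pair from a locally provided core-model SBML
  file, with all case-study parameters (added synthesis stoichiometry,
  knockouts, medium, concave uptake-kinetic pieces, D, default 0.1)
  supplied through `params` rather than hard-coded. Without the file it
  raises an explicit skip signal; nothing is downloaded.

## Numerical choices and limitations

* Sign convention: internally positive `T ν` is uptake (as the balance
  equations are written); the reporting layer (`net_exchange`) flips to
  secretion-positive, abundance-scaled values, the convention of exchange
  plots.
* Tolerances: acceptance 1e-8 (max violation), inner-LP gap 1e-6, dedupe
  1e-6, branch-root tolerance 1e-10, tight-row detection 1e-7.
* Problem sizes in the shipped tests and the acceptance script: exhaustive
  enumeration on the two-species fixtures (branch spaces up to 2^17), grid
  maps of 3×3 to 5×5 with per-point time limits of 10–30 s. Larger grids
  (e.g. 50×50) run through the same API.
* Completeness is exact at the branch level but numerical at the root level:
  a root can in principle escape both the deterministic and the seeded
  Newton starts. The test suite cross-checks the oracle against closed-form
  eliminations and against the independent MILP+LM route.
* The direct non-convex quadratic route (spatial branching on the KKT
  system) is not implemented, and no claim is made that grid-based mapping
  certifies *all* solutions of genome-scale models (grid resolution limits
  apply). ODE stability of the found states is out of scope.
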