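# commsteady

**All metabolically stationary states of microbial community
constraint-based models — without simulating transients.**

Steady-state simulation of a microbial community with flux-balance-type
models needs two assumptions that are usually left implicit: what the
*environment* is (an open chemostat with dilution, or a closed
steady-state batch culture), and who *decides* (each species maximizing its
own growth — a rational agent — or a hypothetical community-level decision
maker maximizing a community objective). `commsteady` implements the four
resulting model classes and finds **all** of their steady states:

| | rational agent | rational community |
|---|---|---|
| **chemostat** | `CA` | `CC` |
| **steady-state batch** | `BA` | `BC` |

It is aimed at computational microbiologists studying coexistence,
crossfeeding and multistability in small consortia and in reduced
genome-scale communities (syntrophic pairs, auxotroph co-cultures,
gut-community toy models).

## The model

Each species *i* carries a stoichiometric matrix (intracellular steady state
`S_i ν_i = 0`), capacity constraints `A_i ν_i ≤ b_i(C)` whose right-hand
sides may be piecewise-linear concave functions of the extracellular
concentrations `C` (uptake kinetics), and an exchange map `T_i`
(`(T_i ν_i)_c` = net uptake of compound *c* per unit biomass). A chemostat
steady state requires

```
D (C_in − C) − Σ_i T_i ν_i X_i = 0        (compound balances)
X_i (D − ν_μ,i) = 0                        (grow at the dilution rate, or be absent)
```

with `ν̂_i = argmax ν_μ,i` per species (CA) or
`ν̂ = argmax Σ_i ν_μ,i X_i` jointly over fluxes *and* concentrations (CC).
In steady-state batch, concentrations disappear, relative abundances `x`
must sum to one, and all present species share one growth rate `μ*` under
culture-level uptake bounds `u`. Because the inner optimizations are linear,
their Karush-Kuhn-Tucker (KKT) conditions are sufficient for global
optimality; replacing the `argmax` by its KKT system turns each model into
one polynomial algebraic system whose solution set *is* the set of steady
states.

Two independent solution routes are provided:

* **Active-set oracle** (`enumerate_solutions`) — exhaustively enumerates
  every complementarity/support branch of the KKT system and solves each
  branch exactly; for small networks this finds *all* steady states.
* **Grid MILP + Levenberg-Marquardt** (`map_grid` → `refine` → `accept` →
  `dedupe`) — fixes the abundance vector to a grid, linearizes complementary
  slackness with binaries and a big-M constant Ω, minimizes equality slacks
  per grid point with a MILP (HiGHS), then releases the abundances and
  polishes each candidate by least squares. Scales to larger models.

Every accepted solution must pass a maximal constraint violation below
1e-8 **and** an independent re-solve of the inner linear program
(optimality gap below 1e-6) — multipliers never certify themselves.

## Worked example

Two species share one substrate S; both need intracellular A and B to grow,
but species 1 makes A at half the yield of species 2 and vice versa — a
metabolic prisoner's dilemma where mutual crossfeeding maximizes community
yield and refusing to secrete maximizes individual yield:

```python
import numpy as np
import commsteady as cs

model = cs.pd_network()
env = cs.EnvironmentSpec(mode="CC", D=0.5, C_in=np.array([10.0, 0.0, 0.0]))
for sol in cs.enumerate_solutions(model, env):
    print(np.round(sol.X, 4), np.round(sol.C, 4), round(sol.nu[0][2], 4))
```

prints (abundances, concentrations `(S, A, B)`, and species 1's B-transport,
negative = secretion):

```
[0. 0.] [10.  0.  0.] -0.0
[0.     2.8333] [1.5 0.  0. ] -0.0
[1.6754 2.1754] [1.2984 0.5    0.5   ] -0.7984
[1.9682 1.9682] [1.127 0.5   0.5  ] -0.627
[2.1754 1.6754] [1.2984 0.5    0.5   ] -0.5
[2.8333 0.    ] [1.5 0.  0. ] -0.0
```

The rational community crossfeeds: in the symmetric state each species
secretes 0.627 units of the compound it makes efficiently, more than the
0.5 its partner takes up, because the chemostat flushes part of it away.
Under the rational-agent model (`mode="CA"`) crossfeeding disappears and the
non-crossfeeding states form a line `X₁ + X₂ = 17/6` at `C_S = 3D`; at a
higher flow rate (`D=1.2`) even the rational community stops secreting.

A command-line layer wraps the same machinery:

```bash
commsteady solve    --config scenario.yaml --out solutions.csv
commsteady map-grid --config scenario.yaml --out solutions.csv
commsteady sweep    --config scenario.yaml --out sweep.csv
```

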