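# fvaprune

Flux variability analysis (FVA) that solves fewer than 2n+1 linear programs
by inspecting intermediate solutions.

## The problem

Flux balance analysis (FBA) predicts steady-state reaction fluxes *v* of a
metabolic network by solving the LP

```
Z0 = max  c'v    s.t.  S v = 0,   lb <= v <= ub
```

where *S* is the m×n stoichiometric matrix, the box bounds encode reaction
reversibility and capacities, and *c* selects the biological objective
(biomass, a product flux). The FBA optimum is usually degenerate, so FVA
characterizes the whole optimal (or near-optimal) face: for each reaction
*i* it computes

```
v_min[i] / v_max[i] = min/max  v_i   s.t.  S v = 0,  c'v >= mu*Z0,  lb <= v <= ub
```

with an optimality fraction `mu` in (0, 1]. Done naively this costs 2n+1
LPs — one FBA plus two extent LPs per reaction.

## The trick

Simplex solvers return a *basic feasible solution*: a vertex with at least
n active constraints. With only m < n equality rows, every vertex must have
fluxes pinned at bounds. Whenever any LP solution in the run pins reaction
*i* at its upper bound, the LP "maximize v_i" is already answered — the
bound is attainable, and no larger extent exists. `fvaprune` inspects every
intermediate vertex (an O(n) scan) and removes such witnessed extent LPs
from the queue, plus two cheap extras: reactions with `lb == ub` need no
LPs at all, and when the objective is a single reaction (`c = a*e_i`) the
phase-1 solve *is* that reaction's extent LP. The extents are identical to
conventional FVA; only the LP count drops.

The LP backend keeps one persistent session per phase (GLPK primal simplex
by default, warm-started from the previous basis; scipy's HiGHS as a
dependency-free alternative; Gurobi optional), so consecutive objectives
re-use the factorized basis.

## Worked example

The built-in fixture is a 7-reaction, 5-metabolite toy network (objective:
maximize `v_4`; reactions 2 and 6 reversible, all bounds ±1e5):

```python
from fvaprune import FVAConfig, example_network, run_fva

result = run_fva(example_network(), FVAConfig(mu=0.9))
```

Running `python examples/01_worked_example.py` prints:

```
Z0 = 0 (phase-1 FBA optimum)

reaction       v_min     v_max  min via    max via
v_1                0    100000  inspected  solved
v_2                0     50000  solved     solved
v_3                0    100000  inspected  inspected
v_4                0         0  inspected  reused
v_5                0         0  inspected  solved
v_6                0    100000  solved     inspected
v_7                0         0  inspected  solved

LPs solved: 7 of 15 conventional (ratio 0.47); removed by inspection: 7, by objective reuse: 1
```

Phase 1 finds Z0 = 0 at v* = 0, which pins the zero lower bounds of
v1, v3, v4, v5, v7 (5 LPs skipped) and doubles as v4's maximization
(1 more). The first upper-bound LP (max v1) lands on a vertex that pins
v3 and v6 at their upper bounds (2 more), so the whole FVA takes 7 LPs
instead of 15. `v_min = 0` for every reaction and
`v_max = <1e5, 5e4, 1e5, 0, 0, 1e5, 0>`, exactly what the conventional
algorithm returns.

Command-line equivalent:

```
fvaprune --example --mu 0.9 --out fva.tsv --stats -
```

Models in COBRA-JSON (as distributed by the BIGG repository) or SBML
L3+FBC load with `fvaprune path/to/model.json` or, from Python,
`fvaprune.load_model(path)`. The other scripts in `examples/` show pruning
statistics on random networks, the exhaustive vertex-enumeration
cross-check, and model file I/O.

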