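# Methods

## Model and problem

A constraint-based metabolic model is the tuple (S, lb, ub, c): the m×n
stoichiometric matrix S (rows are metabolite mass balances, columns are
reactions; consumption negative, production positive, matching the
COBRA-JSON convention), finite or infinite flux bounds, and the objective
vector c of the biological imperative. Phase 1 (FBA) maximizes c'v over
{S v = 0, lb ≤ v ≤ ub} to obtain Z0; phase 2 (FVA) computes, for each
reaction, the minimum and maximum flux over the same polytope intersected
with the optimality-fraction row c'v ≥ mu·Z0, mu ∈ (0, 1].

## The pruning argument and its validity conditions

A bounded, feasible LP attains its optimum at a vertex (basic feasible
solution); a vertex in n variables has at least n active constraints. The
steady-state system contributes only m equalities, so when n > m a vertex
must have at least n − m fluxes pinned at a bound. Any vertex produced
anywhere in the run therefore *witnesses* the attainability of every bound
it pins: if v*[i] sits on ub[i], the LP "maximize v_i" is answered by
ub[i] and is removed from the queue. The inspection scan is a single O(n)
pass per solution over the still-pending task slots (verified by an
operation counter), for O(n²) total overhead — negligible against the LPs
it saves.

Three validity conditions are enforced rather than assumed:

- **Vertex certification.** Only solutions with `is_vertex=True` are
  inspected. The GLPK and Gurobi adapters run simplex, which is basic by
  construction; the HiGHS adapter (scipy `linprog`, dual simplex) is
  additionally certified by counting active constraints (equality rows +
  bounds within tolerance + the optimality row) ≥ n, and degrades to
  `is_vertex=False` — the LP still counts as solved, it just prunes
  nothing — if the certificate fails.
- **Phase-2 feasibility of the witness.** A witness must satisfy
  c'v* ≥ mu·Z0 − eps_feas. Phase-2 solutions satisfy it by construction;
  the phase-1 optimum is checked explicitly, because with Z0 < 0 and
  mu < 1 the literal row mu·Z0 exceeds Z0 and the phase-1 vertex lies
  outside phase 2. The row is kept literal (no sign-aware rewriting); a
  warning is logged in that regime and an empty phase-2 polytope raises an
  explicit infeasibility error.
- **Finite bounds only.** An infinite bound is never "attained"; those
  extent LPs are always solved and may legitimately return ±inf (recorded
  as the extent; a ray is not a vertex, so nothing is inspected).

Objective reuse applies when c = a·e_i for a single reaction: phase 1 then
*is* the maximization (a > 0) or minimization (a < 0) of v_i, with extent
Z0/a; since mu ≤ 1 keeps the phase-1 optimum inside phase 2, the value
carries over.

Reactions with lb == ub have both extents trivially equal to that value at
any feasible point, so a pre-pass removes both tasks without LPs. This
pre-pass is treated as part of pruning and disabled together with
inspection, so the conventional mode solves exactly 2n+1 LPs on every
model — the cleaner accounting baseline.

## Algorithm

1. Pre-pass: remove both tasks of each fixed reaction (witness lb).
2. Phase 1: solve FBA (1 LP). Infeasible or unbounded models abort with
   explicit errors. Apply objective reuse; inspect the phase-1 vertex if
   it passes the phase-2 feasibility check.
3. Phase 2: one persistent LP session; the optimality row is appended to
   the phase-1 session so the basis carries over. Tasks are visited in a
   configurable order (default: all maximizations by ascending reaction
   index, then all minimizations). A task is re-checked immediately before
   solving and skipped if a just-inspected vertex removed it; otherwise
   its LP is solved, the extent recorded, and its vertex inspected against
   all still-pending tasks.
4. Extents of removed tasks are their witness values (the attained bound,
   or Z0/a for reuse). Accounting: lps_solved + lps_removed = 2n + 1.

Extents are order- and solver-independent; the *number* of LPs pruned is
not, because degenerate LPs have many optimal vertices and which one the
simplex returns decides what gets witnessed. No attempt is made to steer
the solver toward maximally bound-touching vertices.

## LP backends

- `glpk` (default when swiglpk is importable): persistent `glp_prob`,
  presolver off so the previous optimal basis warm-starts the next solve.
  Primal simplex is the default method: after an objective change the old
  solution stays primal-feasible, so warm starts help; under dual simplex
  it is generally dual-infeasible, which is why dual is selectable but not
  recommended.
- `highs`: scipy's bundled HiGHS via `linprog` (dual simplex). Stateless —
  scipy exposes no basis handle — but has no extra dependency.
- `gurobi`: optional, requires gurobipy; persistent model, simplex only.

Interior-point methods without crossover are not offered: their solutions
are interior and would disable inspection entirely.

## Tolerances and numerical choices

- Bound attainment: |x − b| ≤ 1e-6 + 1e-9·max(1, |b|). The absolute floor
  matches common LP feasibility defaults; the relative part keeps the test
  meaningful for the 1e5-magnitude bounds typical of genome-scale models.
- Witness phase-2 feasibility slack eps_feas = 1e-6.
- A Z0 more negative than −1e-9 with mu < 1 triggers the tighter-row
  warning; the tolerance avoids warning on −0.0 float noise from the
  solver.
- Cross-route comparisons in tests use 1e-6 absolute + 1e-6 relative.

## Enumeration oracle

`fva_oracle_enumerate` is the solver-independent ground truth for tiny
instances (n ≤ 12, finite bounds): after dropping redundant stoichiometric
rows (QR with column pivoting), it enumerates every basis — choose r basic
variables with a nonsingular submatrix, fix the rest at a bound, solve the
square system (vectorized over all 2^(n−r) bound assignments) — filters
feasible vertices, and takes coordinate-wise extents; phase-2 vertices on
the optimality hyperplane are enumerated from the augmented system
[S; c']. Arithmetic is float64: the generator emits integer coefficients
in {−2, −1, 1, 2} and integer bounds precisely so these small systems are
solved far below the 1e-6 comparison tolerance, keeping the oracle fast
enough to run over a hundred networks in the test suite.

## Synthetic networks

The generator emulates the structural regime the algorithm targets:
n > m ≥ 1, every metabolite produced and consumed somewhere (no trivially
empty rows), integer stoichiometry, a single-reaction indicator objective,
and bounds of magnitude B = 1e5 (mirroring the built-in example) with a
configurable irreversible fraction (default 0.5); 0 always lies within the
bounds, so v = 0 is feasible and the finite box keeps every LP bounded —
generated instances never exercise the infeasible/unbounded error paths,
which are tested with hand-built models instead. It makes no attempt at
biological realism: no compartments, no scale-free degree distribution, no
blocked-pathway structure, and real genome-scale models are far sparser
relative to their size. Passing tests on generated instances therefore
demonstrate correctness of the extents and of the LP accounting, not the
LP-reduction ratios one would observe on curated genome-scale models.

## Problem sizes in the test suite

The property suite runs the three-way comparison (pruned run, conventional
run, enumeration oracle) on the worked example plus 100 seeded random
networks with m ∈ [3, 8] and n ∈ [m+1, 12] — sizes chosen so exhaustive
vertex enumeration stays exact and the whole suite completes in seconds.

## Known limitations

- Serial execution only; no batched or multi-threaded phase 2.
- No MILP support (loop-less FVA variants are out of scope).
- Warm starting is a performance optimization, never relied on for
  correctness; the HiGHS adapter simply does without.
- Pruning counts on real models depend on the solver's vertex selection
  among degenerate optima and are therefore not bit-reproducible across
  solvers or versions; extents are.
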