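# Methods

## Model and problem

A metabolic network is a stoichiometric matrix `S` (M internal metabolites ×
R reactions) with reversibility flags. External metabolites are never rows;
boundary exchange appears as columns with net production or consumption.
Reversible reactions are decomposed into opposing irreversible pairs before
enumeration (`split_reversible`), so the enumerated objects are formally
extreme currents; we call both EFMs. An EFM is a support-minimal solution of
`S·v = 0, v ≥ 0`, unique up to positive scaling; all outputs are normalized
to a minimum positive flux entry of 1 so sets compare exactly across the
search, the oracle and partitioned sub-jobs.

## The elementarity and identification properties

With `NS` an R×DoF basis of null(S), `v = NS·t`. The rank test (nullity of
the support columns of `S` equals one, with a sign-definite null vector) is
equivalent to the flux vector having exactly DoF−1 independent inactive free
fluxes. When the nullspace is put in reduced-row-echelon form with *leading*
pivot rows — pivots chosen greedily in reaction-index order so the pivot-row
submatrix is the identity and the pivot set is the lexicographically
smallest admissible one — each EFM is identified by a unique leading set of
DoF−1 independent inactive rows. The depth-first search enumerates those
identifying sets; the test suite verifies empirically, on every fixture and
on batches of random networks, that emitted identifiers are distinct and
equal the lexicographically smallest rank-(DoF−1) subset of each mode's
inactive reactions.

## Search procedure

State: an ascending IFF list (≤ DoF−1 reactions forced to zero flux), a FAF
list (reactions forced active), an R×(DoF−1) recording matrix whose j-th
column marks reactions forced permanently active by the j-th IFF, and a scan
cursor.

* **Initialization** presets the IFF list to the leading DoF−1 pivot rows
  and scans downstream reactions one at a time as a lone FAF; the first
  feasible candidate yields the initial mode. (If the first pivot is, say,
  the sole substrate uptake, no initial mode exists and the search starts
  with backtracking — this is common and correct.)
* **Forward-tracking** scans reactions after the cursor, skipping FAF and
  marked reactions; a candidate joins the IFF iff its nullspace row is
  independent of the current IFF rows (rank test) and the configuration
  stays LP-feasible. On joining, a per-candidate zero-feasibility analysis
  (equivalent to flux variability analysis for the needed boolean, at half
  the LP calls; a flag switches to classic min-based FVA) marks newly forced
  reactions. At DoF−1 IFF the pinned ray is materialized by the LP and
  emitted.
* **Backtracking** pops the terminal IFF, clears its recording column,
  drops FAF above it, converts it to FAF and tests feasibility; it keeps
  popping on failure. The search terminates when the IFF list empties: a
  configuration with no IFF left and an infeasible FAF conversion cannot
  contain further modes (any mode below it would itself witness
  feasibility), so no final forward pass is needed.

**Check-points** guard every forward extension: (1) enough remaining
candidates to reach DoF−1 IFF; (2) enough independent nullspace rows among
IFF plus candidates; (3) the column submatrix of `S` over (marked ∪ FAF)
reactions must have nullity zero. Nullity one means that active set closes
exactly one candidate mode, and the branch below can contain at most that
mode; it is emitted *only if* the current IFF plus the mode's inactive
reactions downstream of the cursor still reach rank DoF−1 — precisely the
condition under which this branch would have identified the mode without
the shortcut. Otherwise the branch is pruned and the mode's owning branch
emits it; this ownership rule is what makes the early exit consistent with
exactly-once emission (verified against the oracle on every random batch).
Nullity ≥ 2 is not expected under the marking discipline and is pruned
conservatively.

Strict positivity (`v > 0`) is encoded as `v ≥ 1` throughout: valid because
the solution set is a cone, so any strictly positive solution rescales. A
flux bound `v_r ≥ k` with `k > 0` combined with `v_r = 0` is recognized as
infeasible before the LP is built (the LP row encoding would otherwise let
the equality shadow the bound).

## LP backends

All decisions reduce to blank-objective feasibility LPs over `t` (length
DoF, tens of variables at desk scale). Two interchangeable backends are
provided behind one contract: GLPK via swiglpk (default — roughly 8× faster
than HiGHS on these tiny problems) and HiGHS via `scipy.optimize.linprog`.
Solver errors (not infeasibility) are retried once and then raised. The
lp_engine test suite runs on both backends, and end-to-end enumerations are
cross-checked on both; correctness must never be backend-dependent.

## Numerical choices

* Rank decisions use SVD with relative tolerance 1e-10 × the largest column
  norm of the matrix. For row subsets of a nullspace basis the tolerance is
  anchored to the *parent* matrix's column norms, so a numerically-zero row
  of the basis (which `null_space` can produce for reactions outside every
  steady state) never counts as an independent direction.
* RREF runs on floats; pivot rows are snapped to an exact identity and
  entries below 1e-12 to zero. An exact-rational mode is out of scope.
* Support extraction treats `|v| < 1e-9 × max|v|` as zero.
* Bounded LPs (blocked-reaction detection, FVA reduction) cap fluxes at
  1e6; the cone is unbounded, only zero/nonzero matters, and a reaction is
  "blocked" when its bounded maximum falls below 1e-9.
* Ties: the initial-mode scan takes the first feasible FAF candidate;
  candidate scans are in ascending reaction index (after the optional
  row-sorting heuristic, which orders reactions by the product of positive
  and negative entry counts in their nullspace rows, stable with index
  tie-break, and is applied by permuting the network and mapping results
  back).

## Sparse-EFM basis

As an alternative to the rref basis, `sparse_efm_basis` assembles DoF
mutually independent *short modes*: for each pivot reaction (then any
remaining reaction) an LP minimizes total flux subject to
`S·v = 0, v ≥ 0, v_j = 1`; a vertex of that slice is elementary, and a
mode is kept only if it raises the accumulated column rank. Columns whose
(unique, since the columns are independent) activity coefficient can be
negative for some valid flux vector are detected by one LP per column
(`∃ t: NS·t ≥ 0, t_j ≤ −1`) and listed as sign-free; only these are offered
for partitioning with this basis. If DoF independent modes cannot be
assembled the code falls back to the rref basis with a warning.

## Compression

`compress` iterates to a fixed point over: blocked-reaction removal (per
reaction bounded-LP maximum), enzyme-subset lumping (reactions whose
nullspace-basis rows are proportional with positive ratio carry a fixed
flux ratio in every steady state; their columns are summed with those
ratios), duplicate-column merging (columns equal up to a positive factor),
and removal of all-zero metabolite rows. The expansion map is a tree of
AND nodes (fixed-ratio lumps) and OR nodes (duplicate merges) over original
reactions. Expansion of a compressed EFM multiplies fluxes through AND
ratios and branches over OR choices — a duplicate pair yields one original
mode per member — which is exactly what preserves EFM counts through a
compress/expand round trip (oracle-verified on random networks). Lumped
columns are snapped (entries < 1e-9 cleared) so fully internal pathways
compress to a legitimate all-zero column rather than leaving float residue.

## FVA reduction and drain decomposition

`fva_reduce` fixes the uptake flux to one unit, maximizes the objective
flux, pins it at the maximum and retains exactly the reactions whose
per-reaction LP minimum or maximum exceeds 1e-9 in magnitude — the standard
way to cut a genome-scale model down to the sub-network active at maximum
yield. `replace_with_drains` removes a composite (biomass-style) equation
and adds a unit drain per consumed metabolite and a unit source per
produced one, so sub-models can select which components must be producible.

## Synthetic data

The random-network generator emits integer stoichiometries in {−2,−1,1,2}
at a configurable density with one dedicated source and one sink column,
and redraws (bounded retries) until the network admits a nonzero
steady-state flux. It emulates the size regime where an exhaustive
combinatorial oracle is affordable — up to 20 reactions and DoF 6 — not the
structure of curated genome-scale models: no compartments, no cofactor
coupling, no gene rules, and a far higher ratio of blocked or thermodynamically
trivial cycles than curated models show. Passing the oracle-equivalence
suite therefore demonstrates combinatorial correctness of the search, not
performance or numerical behaviour at genome scale. The
`toy_synthetic` worked-example fixture is likewise a *constructed* network
(14 reactions, 8 metabolites, DoF 6, 9 modes, and a designed forced-active
dependency between its first reactions); it is labelled synthetic
everywhere and stands in for the classic worked example of this algorithm
family without claiming to reproduce any published figure.

## Validation problem sizes

The shipped validation suite runs the search against the brute-force oracle
on 100 random networks (R ≤ 20, DoF ≤ 6), partition checks on 20 networks ×
k ∈ {1,2,3} split columns, constrained-vs-filtered checks on 20 networks,
compression round trips on all fixtures plus 20 networks, and a 128-mode
constant-memory run with batch size 8. These sizes keep the full suite in
the tens of seconds on one CPU while exercising every code path; they are
the package's chosen desk-scale study conditions.

## Known limitations

* Genome-scale enumeration is out of reach by design of the problem, not of
  the implementation: complete EFM sets for models with DoF in the dozens
  require cluster-scale CPU time even with exclusive parallel sub-jobs.
  The package ships the machinery (partitioning, resume, per-job files) but
  no scheduler integration.
* Published genome-scale mode counts and yields for the *E. coli* model
  iAF1260 require that external model and large compute; they are not
  bundled and not asserted by the test suite.
* Rank and feasibility tolerances are float heuristics; pathological
  near-degenerate stoichiometries could misclassify a rank decision.
  All emitted modes are re-checked with the elementarity rank test in the
  suite, and an optional duplicate-emission guard (hash of support) can be
  enabled on any run.
* The uniqueness of the leading identifying set is relied upon as proven
  for the unconstrained search and holds empirically in every constrained
  test batch; it is re-verified, not re-proven, here.
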