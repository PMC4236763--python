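# efmdfs — elementary flux modes by LP-guided depth-first search

`efmdfs` enumerates the **elementary flux modes (EFMs)** of a metabolic
network: the support-minimal nonnegative steady-state flux distributions
`v` with `S·v = 0, v ≥ 0`, unique up to positive scaling. EFMs are the
basic functional pathways of a stoichiometric model and are widely used to
analyse network capabilities and to design strains for higher product
yields. The package is aimed at systems-biology practitioners who need
either the complete EFM set of a small-to-medium model or — more usefully at
scale — the **complete subset of EFMs satisfying flux constraints** (for
example, all modes above a product-yield threshold), computed directly
without enumerating everything first.

## The algorithm

Classical enumerators (Double Description variants) iterate over huge sets
of intermediate candidate modes and are memory-bound. `efmdfs` instead
searches over **constraint configurations**. Writing every steady-state
flux as `v = NS·t`, with `NS` an R×DoF nullspace basis of `S`
(DoF = nullity(S)), two facts drive the search:

* a flux vector is elementary iff the submatrix of `S` over its support has
  nullity one — equivalently, iff it has exactly **DoF−1 independent
  inactive free fluxes**;
* with the nullspace in reduced-row-echelon form (pivot rows = identity,
  chosen as the *leading* reactions), each EFM is identified by a **unique
  leading set of DoF−1 inactive free fluxes (IFF)**.

The depth-first search walks these identifying sets with two alternating
moves. *Forward-tracking* scans reactions downstream of the current
terminal IFF and appends any candidate that passes a **rank test** (its
nullspace row is independent of the current IFF rows) and an **LP
feasibility test** (minimize 0 subject to `NS·t = 0` on IFF rows,
`NS·t ≥ 1` on fixed-active rows, `NS·t ≥ 0` elsewhere; strict positivity is
encoded as `≥ 1`, equivalent on a cone). Reaching DoF−1 IFF pins a unique
ray — one EFM. *Backtracking* pops the terminal IFF, converts it to a
fixed-active flux (FAF), clears downstream FAF, and resumes at the first
feasible configuration. A recording matrix marks reactions each new IFF
forces active (skipped as IFF candidates), and three progress check-points
prune branches that cannot reach DoF−1 IFF, including an early exit when
the forced-active set already closes a unique mode.

Because the search holds only its own state and a fixed-size output buffer,
memory is constant in the number of modes. Fixing the sign pattern of k
basis coefficients (`t_j = 0` vs `t_j ≥ 1`) splits the problem into 2^k
**exclusive sub-jobs** that partition the EFM set exactly — embarrassingly
parallel, no coordination needed. Extra flux bounds `v_r ≥ k` restrict the
enumeration to exactly the satisfying subset.

Every claim above is tested against an independent **brute-force oracle**
that enumerates all C(R, DoF−1) reaction subsets and keeps the
sign-definite rays.

## Worked example

The shipped `toy_synthetic` fixture is a constructed 14-reaction,
8-metabolite network (DoF = 6) with one substrate uptake, four routes to a
hub metabolite, two drain routes and a futile two-cycle:

```bash
$ efmdfs enumerate --model src/efmdfs/data/fixtures/toy_synthetic.json --out-dir out
9 EFMs -> out
$ cat out/report.json
{
 "n_efms": 9,
 "lp_calls": 252,
 "rank_tests": 42,
 "efms_per_1000_lp": 35.714,
 ...
}
```

Nine EFMs: eight substrate-to-product routes (4 interior routes × 2 drain
routes) plus the two-cycle `{R11, R14}`. The report counts 252 LP
feasibility tests and 42 rank tests — the entire cost of the enumeration;
no intermediate modes are ever stored. `out/efms_flux.tsv` holds one
normalized flux vector per row (minimum positive entry = 1) and
`out/efms_support.mtx` the sparse binary support matrix.

Constrained enumeration returns exactly the satisfying subset directly:

```bash
$ efmdfs enumerate --model diamond.json --constraint 'vr4>=1' --out-dir out2
1 EFMs -> out2
```

Partitioning and merging (the two sub-jobs find 1 + 1 of the diamond's two
EFMs, verified disjoint):

```bash
$ efmdfs partition --model diamond.json --column 1 --jobs-dir jobs --run
2 job descriptors -> jobs
  job_0: 1 EFMs
  job_1: 1 EFMs
$ efmdfs merge --jobs-dir jobs
  job_0: 1 EFMs
  job_1: 1 EFMs
total: 2 EFMs (supports pairwise distinct)
```

Other subcommands: `compress` (lossless network compression with an
expansion map), `reduce` (FVA reduction at maximum objective yield),
`run-job` (single sub-job, for cluster dispatch), `validate` (cross-check
against the brute-force oracle; nonzero exit on any mismatch).

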