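"""Brute-force reference enumerator, random network generator, and fixtures.

The brute-force oracle inverts the identification property the depth-first
search relies on: every EFM is the unique nonnegative ray obtained by zeroing
some set of DoF-1 reactions whose nullspace-basis rows are independent.
Enumerating all C(R, DoF-1) subsets and keeping the sign-definite rays
therefore yields the complete EFM set — combinatorially expensive, but
completely independent of the LP-driven search it validates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional

import numpy as np
from scipy.linalg import null_space

from .model_io import IrreversibleNetwork, MetabolicNetwork, as_irreversible
from .nullspace_core import numeric_rank
from .records import EFMRecord, EFMSet, normalize_flux, support_of

ORACLE_GUARD = 10_000_000


@dataclass
class FixtureSpec:
    name: str
    network: MetabolicNetwork
    known_efm_count: Optional[int] = None
    provenance: str = "constructed"


def brute_force_efms(net) -> EFMSet:
    """Exhaustive EFM enumeration by scanning (DoF-1)-subsets of reactions.

    For each subset with DoF-1 independent nullspace rows, the zero
    constraints pin a one-dimensional ray; sign-definite rays are kept and
    deduplicated by support.  Fluxes are normalized to a minimum positive
    entry of 1, matching the depth-first search output.
    """
    inet = as_irreversible(net)
    stoich = inet.stoich
    m, r = stoich.shape
    out = EFMSet(list(inet.reaction_ids))
    ns = null_space(stoich) if m else np.eye(r)
    dof = ns.shape[1]
    if dof == 0:
        return out

    def try_ray(v: np.ndarray):
        scale = np.max(np.abs(v))
        if scale == 0:
            return
        v = v / scale
        v[np.abs(v) < 1e-9] = 0.0
        if np.any(v > 0) and np.any(v < 0):
            return
        flux = normalize_flux(np.abs(v))
        rec = EFMRecord(support_of(flux), flux)
        if rec not in out:
            out.add(rec)

    if dof == 1:
        try_ray(ns[:, 0])
        return out
    scale = float(np.max(np.linalg.norm(ns, axis=0)))
    n_subsets = comb(r, dof - 1)
    if n_subsets > ORACLE_GUARD:
        raise ValueError(
            f"C({r},{dof - 1}) = {n_subsets} subsets exceeds the oracle guard; "
            "use the depth-first search for networks of this size")
    for subset in combinations(range(r), dof - 1):
        rows = ns[list(subset), :]
        if numeric_rank(rows, scale=scale) != dof - 1:
            continue
        z = null_space(rows)
        if z.shape[1] != 1:
            continue
        try_ray(ns @ z[:, 0])
    return out


def gen_random_network(n_mets: int, n_rxns: int, density: float = 0.35,
                       seed: int = 0) -> MetabolicNetwork:
    """Deterministic random irreversible network with a source and a sink.

    Coefficients are drawn from {-2, -1, 1, 2}; the generator retries (up to
    100 draws) until the network admits at least one nonzero steady-state
    flux, so every returned network has at least one EFM candidate direction.
    """
    if not (n_rxns > n_mets >= 1):
        raise ValueError("need n_rxns > n_mets >= 1")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    values = np.array([-2.0, -1.0, 1.0, 2.0])
    for _ in range(100):
        stoich = np.zeros((n_mets, n_rxns))
        stoich[rng.integers(n_mets), 0] = 1.0   # source column
        stoich[rng.integers(n_mets), 1] = -1.0  # sink column
        for j in range(2, n_rxns):
            while True:
                mask = rng.random(n_mets) < density
                if mask.any():
                    break
            stoich[mask, j] = rng.choice(values, size=int(mask.sum()))
        if _admits_nonzero_flux(stoich):
            return MetabolicNetwork(
                stoich,
                [f"R{j + 1:02d}" for j in range(n_rxns)],
                [f"M{i + 1:02d}" for i in range(n_mets)],
                np.zeros(n_rxns, dtype=bool))
    raise RuntimeError("no feasible random network after 100 retries")


def _admits_nonzero_flux(stoich: np.ndarray) -> bool:
    from . import lp_engine

    m, r = stoich.shape
    res = lp_engine.solve_raw(-np.ones(r), A_eq=stoich, b_eq=np.zeros(m),
                              bounds=[(0.0, 1.0)] * r)
    return res.status == "optimal" and float(np.sum(res.x)) > 1e-6


def permute_reactions(net: MetabolicNetwork, seed: int) -> MetabolicNetwork:
    """Deterministic column permutation; seed 0 is the identity."""
    r = net.n_reactions
    if seed == 0:
        perm = np.arange(r)
    else:
        perm = np.random.default_rng(seed).permutation(r)
    return MetabolicNetwork(net.stoich[:, perm],
                            [net.reaction_ids[i] for i in perm],
                            list(net.metabolite_ids), net.reversible[perm])


# ---------------------------------------------------------------------------
# Hand-built fixtures
# ---------------------------------------------------------------------------

def _net(met_ids, rxn_ids, entries) -> MetabolicNetwork:
    row = {mid: i for i, mid in enumerate(met_ids)}
    stoich = np.zeros((len(met_ids), len(rxn_ids)))
    for j, terms in enumerate(entries):
        for mid, coef in terms.items():
            stoich[row[mid], j] = coef
    return MetabolicNetwork(stoich, list(rxn_ids), list(met_ids),
                            np.zeros(len(rxn_ids), dtype=bool))


def chain_network() -> MetabolicNetwork:
    """->A, A->B, B-> : a single linear pathway (one EFM)."""
    return _net(["A", "B"], ["R1", "R2", "R3"],
                [{"A": 1}, {"A": -1, "B": 1}, {"B": -1}])


def diamond_network() -> MetabolicNetwork:
    """->A; A->B; A->C; B->D; C->D; D-> : two parallel branches (two EFMs)."""
    return _net(["A", "B", "C", "D"], ["r1", "r2", "r3", "r4", "r5", "r6"],
                [{"A": 1}, {"A": -1, "B": 1}, {"A": -1, "C": 1},
                 {"B": -1, "D": 1}, {"C": -1, "D": 1}, {"D": -1}])


def lossy_diamond_network() -> MetabolicNetwork:
    """Diamond where the A->C branch yields only half a D equivalent."""
    return _net(["A", "B", "C", "D"], ["r1", "r2", "r3", "r4", "r5", "r6"],
                [{"A": 1}, {"A": -1, "B": 1}, {"A": -1, "C": 1},
                 {"B": -1, "D": 1}, {"C": -1, "D": 0.5}, {"D": -1}])


def toy_synthetic_network() -> MetabolicNetwork:
    """Synthetic worked-example network: 14 reactions, 8 internal metabolites.

    This is a *constructed* stand-in (not transcribed from any published
    figure) built to the same headline structure as the classic worked
    example for this algorithm family: M=8, R=14, DoF=6, 9 EFMs, and the
    dependency that when R01 is fixed active and R02 is inactivated, R04 is
    forced active (metabolite A is made by R01 and consumed only by R02 and
    R04).  Four routes lead from the substrate to hub F, two drain routes
    leave it, and R11/R14 form a futile interconversion cycle.
    """
    return _net(
        ["A", "B", "C", "D", "E", "F", "G", "H"],
        [f"R{j:02d}" for j in range(1, 15)],
        [
            {"A": 1},                 # R01: -> A
            {"A": -1, "B": 1},        # R02: A -> B
            {"B": -1, "D": 1},        # R03: B -> D
            {"A": -1, "C": 1},        # R04: A -> C
            {"B": -1, "E": 1},        # R05: B -> E
            {"D": -1, "F": 1},        # R06: D -> F
            {"E": -1, "F": 1},        # R07: E -> F
            {"C": -1, "F": 1},        # R08: C -> F
            {"C": -1, "G": 1},        # R09: C -> G
            {"G": -1, "F": 1},        # R10: G -> F
            {"F": -1, "H": 1},        # R11: F -> H
            {"H": -1},                # R12: H ->
            {"F": -1},                # R13: F ->
            {"H": -1, "F": 1},        # R14: H -> F
        ])


def layered_branch_network(n_stages: int) -> MetabolicNetwork:
    """Chain of metabolites with two parallel reactions per stage: 2^n EFMs."""
    mets = [f"M{i}" for i in range(n_stages + 1)]
    rxn_ids = ["Rin"]
    entries = [{mets[0]: 1}]
    for i in range(n_stages):
        for tag in ("a", "b"):
            rxn_ids.append(f"S{i}{tag}")
            entries.append({mets[i]: -1, mets[i + 1]: 1})
    rxn_ids.append("Rout")
    entries.append({mets[-1]: -1})
    return _net(mets, rxn_ids, entries)


def get_fixture(name: str) -> FixtureSpec:
    builders = {
        "chain": (chain_network, 1),
        "diamond": (diamond_network, 2),
        "toy_synthetic": (toy_synthetic_network, 9),
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}")
    fn, count = builders[name]
    return FixtureSpec(name, fn(), count, "constructed")
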