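"""Depth-first enumeration of elementary flux modes.

The search walks constraint configurations (IFF = reactions forced to zero,
FAF = reactions forced active) instead of intermediate modes.  An EFM is
identified by its leading DoF-1 independent inactive free fluxes, so the
enumeration alternates two moves:

* forward-tracking scans reactions downstream of the previous terminal IFF
  and adds every candidate that passes a rank test (its nullspace row is
  independent of the current IFF rows) and an LP feasibility test; reaching
  DoF-1 IFF pins a unique ray — an EFM;
* backtracking pops the terminal IFF, clears downstream FAF, converts the
  popped reaction to FAF, and resumes forward-tracking at the first feasible
  configuration.

Speed-ups: a recording matrix marks reactions that each new IFF forces
active (they are skipped as IFF candidates while the mark stands), and three
progress check-points prune branches that cannot reach DoF-1 IFF; when the
column submatrix over (marked + FAF) reactions has nullity exactly one, that
branch has already found an EFM and forward-tracking exits early.

Memory is constant in the number of modes: emitted records go through a
fixed-size buffer to an output sink.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from scipy.linalg import null_space

from . import lp_engine
from .lp_engine import ConstraintSet
from .model_io import IrreversibleNetwork, MetabolicNetwork, as_irreversible
from .nullspace_core import (NullspaceBasis, compute_nsrref,
                             leading_independent_rows, numeric_rank,
                             sort_rows_heuristic)
from .records import EFMRecord, EFMSet, normalize_flux, support_of

DEFAULT_BATCH_SIZE = 10_000


@dataclass
class SearchState:
    """The DFS's entire mutable state.

    ``iff`` is strictly increasing (insertion order equals index order);
    ``m_record`` column j holds the reactions marked permanently active by
    the j-th IFF; ``cursor`` is the last scanned reaction index.
    """

    iff: list[int]
    faf: list[int]
    m_record: np.ndarray
    cursor: int
    phase: str  # "forward" | "backward" | "done"

    def marked(self) -> np.ndarray:
        if self.m_record.shape[1] == 0:
            return np.zeros(self.m_record.shape[0], dtype=bool)
        return self.m_record.any(axis=1)

    def to_json(self) -> str:
        return json.dumps({"iff": self.iff, "faf": self.faf, "cursor": self.cursor,
                           "phase": self.phase})


class DuplicateEmissionError(AssertionError):
    """The search emitted the same support twice (violates the uniqueness theorem)."""


class NullSink:
    def append(self, batch):  # pragma: no cover - trivial
        pass

    def finalize(self):  # pragma: no cover - trivial
        pass


@dataclass
class EnumerationResult:
    efms: Optional[EFMSet]
    n_efms: int
    counters: dict
    snapshot: Optional[str] = None  # JSON SearchState when stopped early


class DepthFirstEnumerator:
    """Single-tree depth-first EFM search over one constraint set."""

    def __init__(self, net, cs: Optional[ConstraintSet] = None,
                 basis: Optional[NullspaceBasis] = None, backend=None,
                 check_duplicates: bool = False):
        self.inet = as_irreversible(net)
        self.stoich = self.inet.stoich
        self.n_reactions = self.stoich.shape[1]
        self.cs = cs or ConstraintSet()
        self.basis = basis if basis is not None else compute_nsrref(self.stoich)
        self.dof = self.basis.dof
        self.backend = backend
        self.counters = {"lp_calls": 0, "rank_tests": 0, "efms": 0}
        self._ns_scale = (float(np.max(np.linalg.norm(self.basis.ns, axis=0)))
                          if self.dof else 0.0)
        self._seen: Optional[set[bytes]] = set() if check_duplicates else None

    # -- LP helpers --------------------------------------------------------

    def _config(self, state: SearchState, extra_iff=(), extra_faf=()) -> ConstraintSet:
        return ConstraintSet(self.cs.iff | set(state.iff) | set(extra_iff),
                             (self.cs.faf | set(state.faf) | set(extra_faf))
                             - (self.cs.iff | set(state.iff) | set(extra_iff)),
                             self.cs.flux_bounds, self.cs.t_signs)

    def _feasible(self, state: SearchState, extra_iff=(), extra_faf=()) -> bool:
        new_iff = self.cs.iff | set(state.iff) | set(extra_iff)
        faf = self.cs.faf | set(state.faf) | set(extra_faf)
        if new_iff & faf:
            return False  # a zero-forced reaction cannot also be active-forced
        cs = ConstraintSet(new_iff, faf, self.cs.flux_bounds, self.cs.t_signs)
        return lp_engine.feasible(self.basis, cs, self.backend, self.counters)

    def _rank_adds(self, iff: list[int], candidate: int) -> bool:
        self.counters["rank_tests"] += 1
        rows = self.basis.ns[iff, :] if iff else np.empty((0, self.dof))
        base = numeric_rank(rows, scale=self._ns_scale)
        return numeric_rank(np.vstack([rows, self.basis.ns[candidate]]),
                            scale=self._ns_scale) == base + 1

    # -- record construction ----------------------------------------------

    def _emit(self, state: SearchState) -> EFMRecord:
        """Materialize the unique ray pinned by the current DoF-1 IFF."""
        flux = lp_engine.realize(self.basis, self._config(state), self.backend,
                                 self.counters).values
        flux = normalize_flux(flux)
        return self._record(flux, frozenset(state.iff))

    def _record(self, flux: np.ndarray, iff_set: frozenset) -> EFMRecord:
        rec = EFMRecord(support_of(flux), flux, iff_set)
        if self._seen is not None:
            key = rec.support_key()
            if key in self._seen:
                raise DuplicateEmissionError(
                    f"support emitted twice: {np.flatnonzero(rec.support).tolist()}")
            self._seen.add(key)
        self.counters["efms"] += 1
        return rec

    def _early_exit_record(self, state: SearchState,
                           active: list[int]) -> Optional[EFMRecord]:
        """EFM whose support lies inside the nullity-1 active column set.

        A forced-active set with nullity one admits exactly one candidate
        mode, so the branch below this point can contain at most that one
        EFM.  It is emitted here only when the branch could still have
        identified it the ordinary way, i.e. when the current IFF plus the
        mode's inactive reactions downstream of the cursor reach rank DoF-1;
        otherwise some other branch owns the mode and this one is barren.
        """
        vec = null_space(self.stoich[:, active]) if self.stoich.shape[0] \
            else np.eye(len(active))
        if vec.shape[1] != 1:
            return None
        w = vec[:, 0]
        w = w / np.max(np.abs(w))
        if np.any(w > 1e-9) and np.any(w < -1e-9):
            return None  # not signable nonnegative: no mode here
        w = np.abs(w)
        flux = np.zeros(self.n_reactions)
        flux[active] = w
        flux = normalize_flux(flux)
        supp = support_of(flux)
        if any(supp[i] != (i in set(active)) for i in active):
            return None  # ray vanishes on a forced-active reaction: dead branch
        iff_now = set(state.iff)
        reachable = sorted(iff_now) + [q for q in range(state.cursor, self.n_reactions)
                                       if not supp[q] and q not in iff_now]
        if numeric_rank(self.basis.ns[reachable, :], scale=self._ns_scale) < self.dof - 1:
            return None  # this branch cannot pin the mode; its owner will
        # the structural ray must still satisfy the user's constraint set
        if any(not supp[i] for i in self.cs.faf):
            return None
        if any(k > 0 and not supp[i] for i, k in self.cs.flux_bounds):
            return None
        if any(supp[i] for i in self.cs.iff):
            return None
        inactive = [i for i in range(self.n_reactions) if not supp[i]]
        iff_set = frozenset(leading_independent_rows(
            self.basis.ns, self.dof - 1, candidates=inactive))
        return self._record(flux, iff_set)

    # -- the three subroutines ---------------------------------------------

    def initialize(self) -> tuple[SearchState, Optional[EFMRecord]]:
        """Preset the IFF vector to the leading DoF-1 pivot rows and scan
        downstream reactions one at a time as a lone FAF; the first feasible
        one yields the initial EFM."""
        iff = list(self.basis.pivot_rows[:max(self.dof - 1, 0)])
        m_record = np.zeros((self.n_reactions, max(self.dof - 1, 0)), dtype=np.int8)
        state = SearchState(iff, [], m_record, iff[-1] if iff else -1, "forward")
        record = None
        iff_set = set(iff)
        for r in range(state.cursor + 1, self.n_reactions):
            if r in iff_set or r in self.cs.iff:
                continue
            if self._feasible(state, extra_faf=(r,)):
                state.faf = [r]
                record = self._emit(state)
                break
        state.phase = "backward"
        return state, record

    def back_track(self, state: SearchState) -> None:
        """Pop terminal IFFs, converting each to FAF, until a feasible
        configuration is found; the search ends when the IFF vector empties.

        An infeasible configuration with the IFF vector empty cannot emit
        anything in a further forward pass (any mode it found would witness
        feasibility), so exhaustion of the IFF vector terminates the search.
        """
        while state.iff:
            j = state.iff.pop()
            state.m_record[:, len(state.iff)] = 0
            state.faf = [f for f in state.faf if f < j] + [j]
            state.cursor = j
            if self._feasible(state):
                state.phase = "forward"
                return
        state.phase = "done"

    def check_points(self, state: SearchState, scan_from: int) -> str:
        """Progress check-points guarding forward-tracking.

        Returns "proceed", "prune", or "efm_found" (the early exit: the
        marked+FAF column submatrix has nullity exactly one).
        """
        marked = state.marked()
        iff_set = set(state.iff)
        faf_set = set(state.faf) | set(self.cs.faf)
        candidates = [q for q in range(scan_from, self.n_reactions)
                      if q not in iff_set and q not in faf_set and not marked[q]]
        # (1) enough downstream reactions to reach DoF-1 IFF
        if len(state.iff) + len(candidates) < self.dof - 1:
            return "prune"
        # (2) enough *independent* rows among existing + candidate IFF
        rows = sorted(iff_set) + candidates
        if numeric_rank(self.basis.ns[rows, :], scale=self._ns_scale) < self.dof - 1:
            return "prune"
        # (3) the forced-active set must not already close a flux mode
        active = sorted(set(np.flatnonzero(marked)) | faf_set)
        if active:
            null_dim = len(active) - numeric_rank(self.stoich[:, active])
            if null_dim == 1:
                return "efm_found"
            if null_dim >= 2:
                return "prune"  # conservative: nullity >= 2 is unexpected here
        return "proceed"

    def forward_track(self, state: SearchState) -> Optional[EFMRecord]:
        """Scan reactions downstream of the cursor, adding IFF candidates that
        pass the rank and feasibility tests; emits an EFM at DoF-1 IFF or on
        the check-point-3 early exit."""
        record = None
        start = state.cursor + 1
        marked = state.marked()
        faf_set = set(state.faf)
        iff_set = set(state.iff)
        for r in range(start, self.n_reactions):
            state.cursor = r
            if r in faf_set or r in iff_set or marked[r]:
                continue
            cp = self.check_points(state, r)
            if cp == "prune":
                break
            if cp == "efm_found":
                active = sorted(set(np.flatnonzero(marked)) | faf_set | set(self.cs.faf))
                record = self._early_exit_record(state, active)
                break
            if not self._rank_adds(state.iff, r):
                continue
            if not self._feasible(state, extra_iff=(r,)):
                continue
            state.iff.append(r)
            iff_set.add(r)
            if len(state.iff) == self.dof - 1:
                record = self._emit(state)
                break
            # mark reactions this IFF forces permanently active
            col = len(state.iff) - 1
            cands = [q for q in range(self.n_reactions)
                     if q not in iff_set and q not in faf_set and not marked[q]
                     and q not in self.cs.iff]
            forced = lp_engine.forced_active(self.basis, self._config(state), cands,
                                             self.backend, self.counters)
            for q in forced:
                state.m_record[q, col] = 1
            marked = state.marked()
        state.phase = "backward"
        return record

    # -- drivers ------------------------------------------------------------

    def search(self, resume: Optional[SearchState] = None) -> Iterator[EFMRecord]:
        """Yield every EFM satisfying the constraint set exactly once."""
        if self.dof == 0:
            return
        if resume is None:
            state, first = self.initialize()
            if first is not None:
                yield first
            if self.dof == 1:
                return  # a one-dimensional nullspace holds at most one mode
        else:
            state = resume
            if self.dof == 1:
                return
        while state.phase != "done":
            if state.phase == "backward":
                self.back_track(state)
            else:
                rec = self.forward_track(state)
                if rec is not None:
                    yield rec
        self._state = state

    def run(self, sink=None, batch_size: int = DEFAULT_BATCH_SIZE,
            collect: bool = True, resume: Optional[SearchState] = None,
            stop_after: Optional[int] = None) -> EnumerationResult:
        """Drive the search, flushing records to the sink in batches.

        ``collect=False`` keeps the retained record count bounded by the
        batch size regardless of how many modes exist.  ``stop_after``
        interrupts the search after that many emissions and returns a
        resumable JSON snapshot.
        """
        sink = sink or NullSink()
        out = EFMSet(list(self.inet.reaction_ids)) if collect else None
        buffer: list[EFMRecord] = []
        self.counters["max_buffered"] = 0
        n = 0
        snapshot = None
        gen = self.search(resume=resume)
        for rec in gen:
            buffer.append(rec)
            self.counters["max_buffered"] = max(self.counters["max_buffered"], len(buffer))
            if collect:
                out.add(rec)
            n += 1
            if len(buffer) >= batch_size:
                sink.append(buffer)
                buffer = []
            if stop_after is not None and n >= stop_after:
                state = _current_state(gen)
                snapshot = state.to_json() if state is not None else None
                gen.close()
                break
        if buffer:
            sink.append(buffer)
        sink.finalize()
        return EnumerationResult(out, n, dict(self.counters), snapshot)


def _current_state(gen) -> Optional[SearchState]:
    frame = getattr(gen, "gi_frame", None)
    if frame is not None and "state" in frame.f_locals:
        return frame.f_locals["state"]
    return None


def load_state(doc: str, enumerator: DepthFirstEnumerator) -> SearchState:
    """Rebuild a SearchState from its JSON snapshot.

    The recording matrix is not serialized; it is recomputed by replaying the
    forced-active analysis for each IFF in insertion (== index) order, using
    for the j-th IFF the FAF entries below it — exactly the FAF context that
    held when that IFF joined.
    """
    data = json.loads(doc)
    r = enumerator.n_reactions
    state = SearchState(list(data["iff"]), list(data["faf"]),
                        np.zeros((r, max(enumerator.dof - 1, 0)), dtype=np.int8),
                        int(data["cursor"]), data["phase"])
    marked = np.zeros(r, dtype=bool)
    for pos, j in enumerate(state.iff):
        hist_iff = state.iff[:pos + 1]
        hist_faf = [f for f in state.faf if f < j]
        cs = ConstraintSet(enumerator.cs.iff | set(hist_iff),
                           (enumerator.cs.faf | set(hist_faf)) - enumerator.cs.iff,
                           enumerator.cs.flux_bounds, enumerator.cs.t_signs)
        cands = [q for q in range(r)
                 if q not in hist_iff and q not in hist_faf and not marked[q]
                 and q not in enumerator.cs.iff]
        forced = lp_engine.forced_active(enumerator.basis, cs, cands,
                                         enumerator.backend, enumerator.counters)
        for q in forced:
            state.m_record[q, pos] = 1
            marked[q] = True
    return state


def enumerate_efms(net, cs: Optional[ConstraintSet] = None, *,
                   basis_kind: str = "rref", sort_rows: bool = False,
                   backend=None, sink=None, batch_size: int = DEFAULT_BATCH_SIZE,
                   collect: bool = True, check_duplicates: bool = False,
                   resume_snapshot: Optional[str] = None,
                   stop_after: Optional[int] = None) -> EnumerationResult:
    """Enumerate all EFMs of an irreversible network satisfying ``cs``.

    ``sort_rows`` applies the positive-times-negative row-count heuristic
    before searching (results are reported in the original reaction order).
    ``basis_kind`` selects the rref or the sparse-EFM nullspace basis.
    """
    inet = as_irreversible(net)
    cs = cs or ConstraintSet()
    perm = None
    if sort_rows:
        perm = sort_rows_heuristic(compute_nsrref(inet.stoich))
        if np.array_equal(perm, np.arange(inet.n_reactions)):
            perm = None
    if perm is not None:
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        pnet = MetabolicNetwork(inet.stoich[:, perm],
                                [inet.reaction_ids[i] for i in perm],
                                list(inet.metabolite_ids),
                                np.zeros(perm.size, dtype=bool))
        pcs = ConstraintSet(frozenset(int(inv[i]) for i in cs.iff),
                            frozenset(int(inv[i]) for i in cs.faf),
                            tuple((int(inv[i]), k) for i, k in cs.flux_bounds),
                            cs.t_signs)
        inner = enumerate_efms(pnet, pcs, basis_kind=basis_kind, sort_rows=False,
                               backend=backend, batch_size=batch_size,
                               collect=True, check_duplicates=check_duplicates)
        out = EFMSet(list(inet.reaction_ids))
        for rec in inner.efms:
            flux = np.zeros(perm.size)
            flux[perm] = rec.flux
            out.add(EFMRecord(support_of(flux), flux,
                              frozenset(int(perm[i]) for i in rec.iff_set)))
        if sink is not None:
            sink.append(out.records)
            sink.finalize()
        return EnumerationResult(out, len(out), inner.counters)

    basis = None
    if basis_kind == "efm":
        from .nullspace_core import sparse_efm_basis
        basis = sparse_efm_basis(inet, backend=backend)
    elif basis_kind != "rref":
        raise ValueError(f"unknown basis kind {basis_kind!r}")
    enum = DepthFirstEnumerator(inet, cs, basis=basis, backend=backend,
                                check_duplicates=check_duplicates)
    resume = load_state(resume_snapshot, enum) if resume_snapshot else None
    return enum.run(sink=sink, batch_size=batch_size, collect=collect,
                    resume=resume, stop_after=stop_after)
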