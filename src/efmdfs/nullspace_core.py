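"""Nullspace bases, rank tests, the elementarity test, and row-ordering heuristics.

Every steady-state flux vector can be written ``v = NS @ t`` where the columns
of ``NS`` span the nullspace of the stoichiometric matrix and ``t`` has length
DoF (the nullity of S).  The reduced-row-echelon basis ``NS_rref`` is
normalized so that the rows of a greedily chosen leading set of DoF reactions
(the pivot rows, i.e. the free fluxes) form the identity matrix; the
coefficients ``t`` then equal the fluxes of the pivot reactions and are
nonnegative whenever ``v >= 0``.

The elementarity test used throughout: a nonzero flux vector is elementary
iff the column submatrix of S over its support has nullity one (equivalently,
the vector has exactly DoF-1 independent inactive free fluxes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.linalg import null_space

#: Relative tolerance for numeric rank decisions (scaled by the largest
#: column norm of the matrix under test).
RANK_RTOL = 1e-10


def numeric_rank(a: np.ndarray, rtol: float = RANK_RTOL,
                 scale: Optional[float] = None) -> int:
    """Rank by SVD with a tolerance relative to the largest column norm.

    When testing row subsets of a larger matrix, pass the parent matrix's
    largest column norm as ``scale`` so that numerically-zero rows of the
    parent never count as independent directions.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.size == 0:
        return 0
    if scale is None:
        scale = float(np.max(np.linalg.norm(a, axis=0)))
    if scale == 0.0:
        return 0
    s = np.linalg.svd(a, compute_uv=False)
    return int(np.sum(s > rtol * scale))


def nullity(a: np.ndarray) -> int:
    a = np.atleast_2d(np.asarray(a, dtype=float))
    return a.shape[1] - numeric_rank(a)


@dataclass
class NullspaceBasis:
    """R x DoF nullspace basis with pivot bookkeeping.

    ``kind`` is "rref" for the reduced-row-echelon form (pivot rows = exact
    identity, all t >= 0 on the flux cone) or "efm" for a sparse basis whose
    columns are themselves elementary modes; for the latter,
    ``sign_free_columns`` lists columns whose activity coefficient may be
    negative for some valid flux vector.
    """

    ns: np.ndarray
    pivot_rows: list[int]
    dof: int
    kind: str = "rref"
    sign_free_columns: list[int] = field(default_factory=list)

    @property
    def n_reactions(self) -> int:
        return self.ns.shape[0]

    def validate(self, stoich: np.ndarray) -> None:
        if self.dof != self.ns.shape[1]:
            raise ValueError("dof does not match basis column count")
        if self.dof:
            norms = np.linalg.norm(self.ns, axis=0)
            normed = self.ns / np.where(norms > 0, norms, 1.0)
            resid = np.max(np.abs(stoich @ normed)) if stoich.size else 0.0
            if resid > 1e-8:
                raise ValueError(f"basis does not span null(S): residual {resid:.2e}")
            if numeric_rank(self.ns) != self.dof:
                raise ValueError("basis columns are not independent")
        if self.kind == "rref" and self.pivot_rows:
            sub = self.ns[self.pivot_rows, :]
            if not np.array_equal(sub, np.eye(self.dof)):
                raise ValueError("pivot rows of an rref basis must be the identity")


def leading_independent_rows(ns: np.ndarray, count: int,
                             candidates: Optional[Iterable[int]] = None) -> list[int]:
    """Greedy scan in index order for `count` rows of ns with full rank.

    Returns the lexicographically smallest admissible index set.
    """
    rows: list[int] = []
    if count == 0:
        return rows
    scale = float(np.max(np.linalg.norm(ns, axis=0))) if ns.size else 0.0
    idx = range(ns.shape[0]) if candidates is None else sorted(candidates)
    stacked = np.empty((0, ns.shape[1]))
    for i in idx:
        trial = np.vstack([stacked, ns[i]])
        if numeric_rank(trial, scale=scale) == len(rows) + 1:
            rows.append(i)
            stacked = trial
            if len(rows) == count:
                return rows
    raise ValueError(f"only {len(rows)} independent rows available, {count} requested")


def compute_nsrref(stoich: np.ndarray) -> NullspaceBasis:
    """Reduced-row-echelon nullspace basis with leading pivot rows.

    Pivots are chosen greedily in reaction-index order, so the pivot-row
    submatrix is the identity after normalization and the pivot set is the
    lexicographically smallest admissible one.
    """
    stoich = np.atleast_2d(np.asarray(stoich, dtype=float))
    r = stoich.shape[1]
    if r == 0:
        raise ValueError("empty stoichiometric matrix")
    raw = null_space(stoich) if stoich.shape[0] else np.eye(r)
    dof = raw.shape[1]
    if dof == 0:
        return NullspaceBasis(np.zeros((r, 0)), [], 0, "rref")
    pivots = leading_independent_rows(raw, dof)
    ns = raw @ np.linalg.inv(raw[pivots, :])
    ns[pivots, :] = np.eye(dof)  # snap to exact identity
    ns[np.abs(ns) < 1e-12] = 0.0
    return NullspaceBasis(ns, pivots, dof, "rref")


def rank_adds(iff_rows: Iterable[int], candidate: int, basis: NullspaceBasis) -> bool:
    """True iff the candidate's ns row is independent of the iff rows."""
    rows = sorted(iff_rows)
    if candidate in rows:
        raise ValueError("candidate already among the iff rows")
    scale = float(np.max(np.linalg.norm(basis.ns, axis=0))) if basis.dof else 0.0
    base = numeric_rank(basis.ns[rows, :], scale=scale) if rows else 0
    return numeric_rank(basis.ns[rows + [candidate], :], scale=scale) == base + 1


def _active_indices(support, n: Optional[int] = None) -> list[int]:
    if hasattr(support, "active"):
        return sorted(support.active)
    if isinstance(support, (set, frozenset)):
        return sorted(int(i) for i in support)
    arr = np.asarray(support)
    if arr.dtype == bool:
        return list(np.flatnonzero(arr))
    return sorted(int(i) for i in arr)


@dataclass(frozen=True)
class Support:
    """Active/inactive split of the reaction index set."""

    active: frozenset
    inactive: frozenset

    @classmethod
    def from_active(cls, active: Iterable[int], n_reactions: int) -> "Support":
        act = frozenset(int(i) for i in active)
        return cls(act, frozenset(range(n_reactions)) - act)


def is_elementary(support, stoich: np.ndarray) -> bool:
    """Rank test for elementarity of a support set.

    True iff the column submatrix of S over the active reactions has nullity
    one and its one-dimensional nullspace vector can be signed strictly
    positive on every active reaction.
    """
    stoich = np.atleast_2d(np.asarray(stoich, dtype=float))
    active = _active_indices(support)
    if not active:
        return False
    sub = stoich[:, active]
    if len(active) - numeric_rank(sub) != 1:
        return False
    vec = null_space(sub)
    if vec.shape[1] != 1:
        return False
    v = vec[:, 0]
    scale = np.max(np.abs(v))
    if scale == 0:
        return False
    v = v / scale
    if np.min(np.abs(v)) <= 1e-9:
        return False  # an entry vanishes: the true support is smaller
    return bool(np.all(v > 0) or np.all(v < 0))


def sort_rows_heuristic(basis: NullspaceBasis) -> np.ndarray:
    """Reaction permutation by ascending positive-times-negative row counts.

    Rows of the nullspace basis with few possible sign combinations sort
    first; ties keep original order.  Re-run :func:`compute_nsrref` on the
    permuted stoichiometric matrix before searching.
    """
    pos = np.sum(basis.ns > 0, axis=1)
    neg = np.sum(basis.ns < 0, axis=1)
    return np.argsort(pos * neg, kind="stable")


def sparse_efm_basis(net, backend=None) -> NullspaceBasis:
    """Assemble a basis of DoF mutually independent short elementary modes.

    For each pivot reaction (then any remaining reaction) an LP minimizes the
    total flux subject to ``S v = 0, v >= 0, v_j = 1``; a vertex of that
    polyhedron is an elementary mode.  A mode is kept only if it raises the
    rank of the accumulating basis.  Falls back to the rref basis with a
    warning when DoF independent modes cannot be assembled.
    """
    from . import lp_engine
    from .model_io import IrreversibleNetwork

    stoich = net.stoich if isinstance(net, IrreversibleNetwork) else net.stoich
    rref = compute_nsrref(stoich)
    if rref.dof == 0:
        return rref
    m, r = stoich.shape
    order = list(rref.pivot_rows) + [j for j in range(r) if j not in rref.pivot_rows]
    cols: list[np.ndarray] = []
    for j in order:
        if len(cols) == rref.dof:
            break
        c = np.ones(r)
        bounds = [(0.0, None)] * r
        bounds[j] = (1.0, 1.0)
        res = lp_engine.solve_raw(c, A_eq=stoich if m else None,
                                  b_eq=np.zeros(m) if m else None,
                                  bounds=bounds, backend=backend)
        if res.status != "optimal":
            continue
        v = np.asarray(res.x, dtype=float)
        v[np.abs(v) < 1e-9 * max(1.0, np.max(np.abs(v)))] = 0.0
        if not is_elementary(np.flatnonzero(v), stoich):
            continue
        trial = np.column_stack(cols + [v]) if cols else v[:, None]
        if numeric_rank(trial) == len(cols) + 1:
            cols.append(v)
    if len(cols) < rref.dof:
        warnings.warn(
            f"sparse EFM basis assembly found only {len(cols)} of {rref.dof} "
            "independent modes; falling back to the rref basis")
        return rref
    ns = np.column_stack(cols)
    pivots = leading_independent_rows(ns, rref.dof)
    sign_free = _sign_free_columns(ns, backend)
    return NullspaceBasis(ns, pivots, rref.dof, "efm", sign_free)


def _sign_free_columns(ns: np.ndarray, backend=None) -> list[int]:
    """Columns whose (unique) activity coefficient is negative for some v >= 0.

    Because the basis columns are independent, every spanned flux vector has a
    unique coefficient vector t; column j is sign-free iff the cone
    ``{t : NS t >= 0}`` contains a point with ``t_j <= -1``.
    """
    from . import lp_engine

    r, dof = ns.shape
    out = []
    for j in range(dof):
        bounds = [(None, None)] * dof
        bounds[j] = (None, -1.0)
        res = lp_engine.solve_raw(np.zeros(dof), A_ub=-ns, b_ub=np.zeros(r),
                                  bounds=bounds, backend=backend)
        if res.status in ("optimal", "unbounded"):
            out.append(j)
    return out
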