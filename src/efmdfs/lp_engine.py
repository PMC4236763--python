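"""Solver-agnostic LP services for the depth-first EFM search.

All search decisions reduce to one question: does a coefficient vector ``t``
exist with ``NS t = 0`` on the inactive (IFF) rows, ``NS t >= 1`` on the
fixed-active (FAF) rows, ``NS t >= k`` for extra flux bounds, and
``NS t >= 0`` elsewhere?  The strict inequality "flux > 0" is encoded as
">= 1", which is equivalent on a cone because any strictly positive solution
can be rescaled.  The LP objective is blank (feasibility only).

Two interchangeable backends are provided: GLPK (via swiglpk, the default —
fastest on the many tiny LPs this tool solves) and HiGHS (via
scipy.optimize.linprog).  Correctness must never depend on the backend.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

from .nullspace_core import NullspaceBasis, numeric_rank
from .records import SUPPORT_ZERO_RTOL, normalize_flux, support_of


class BackendError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    x: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------

class ScipyHighsBackend:
    """HiGHS via scipy.optimize.linprog."""

    name = "highs"

    def solve(self, c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None) -> LPResult:
        from scipy.optimize import linprog

        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        if res.status == 0:
            return LPResult("optimal", np.asarray(res.x, dtype=float))
        if res.status == 2:
            return LPResult("infeasible")
        if res.status == 3:
            return LPResult("unbounded")
        return LPResult("error")


class GlpkBackend:
    """GLPK via swiglpk (primal simplex, terminal output off)."""

    name = "glpk"

    def __init__(self):
        import swiglpk as glp

        self._glp = glp
        glp.glp_term_out(glp.GLP_OFF)
        self._parm = glp.glp_smcp()
        glp.glp_init_smcp(self._parm)
        self._parm.msg_lev = glp.GLP_MSG_OFF

    def solve(self, c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None) -> LPResult:
        glp = self._glp
        c = np.asarray(c, dtype=float)
        n = c.size
        n_ub = 0 if A_ub is None else np.atleast_2d(A_ub).shape[0]
        n_eq = 0 if A_eq is None else np.atleast_2d(A_eq).shape[0]
        lp = glp.glp_create_prob()
        try:
            glp.glp_set_obj_dir(lp, glp.GLP_MIN)
            glp.glp_add_cols(lp, n)
            if bounds is None:
                bounds = [(0.0, None)] * n
            for j, (lo, hi) in enumerate(bounds, start=1):
                if lo is None and hi is None:
                    glp.glp_set_col_bnds(lp, j, glp.GLP_FR, 0.0, 0.0)
                elif hi is None:
                    glp.glp_set_col_bnds(lp, j, glp.GLP_LO, float(lo), 0.0)
                elif lo is None:
                    glp.glp_set_col_bnds(lp, j, glp.GLP_UP, 0.0, float(hi))
                elif lo == hi:
                    glp.glp_set_col_bnds(lp, j, glp.GLP_FX, float(lo), float(hi))
                else:
                    glp.glp_set_col_bnds(lp, j, glp.GLP_DB, float(lo), float(hi))
            for j in range(n):
                if c[j]:
                    glp.glp_set_obj_coef(lp, j + 1, float(c[j]))
            n_rows = n_ub + n_eq
            if n_rows:
                glp.glp_add_rows(lp, n_rows)
                entries = []
                if n_ub:
                    a_ub = np.atleast_2d(np.asarray(A_ub, dtype=float))
                    b_ub_arr = np.atleast_1d(np.asarray(b_ub, dtype=float))
                    for i in range(n_ub):
                        glp.glp_set_row_bnds(lp, i + 1, glp.GLP_UP, 0.0, float(b_ub_arr[i]))
                        for j in np.flatnonzero(a_ub[i]):
                            entries.append((i + 1, int(j) + 1, float(a_ub[i, j])))
                if n_eq:
                    a_eq = np.atleast_2d(np.asarray(A_eq, dtype=float))
                    b_eq_arr = np.atleast_1d(np.asarray(b_eq, dtype=float))
                    for i in range(n_eq):
                        glp.glp_set_row_bnds(lp, n_ub + i + 1, glp.GLP_FX,
                                             float(b_eq_arr[i]), float(b_eq_arr[i]))
                        for j in np.flatnonzero(a_eq[i]):
                            entries.append((n_ub + i + 1, int(j) + 1, float(a_eq[i, j])))
                nz = len(entries)
                ia = glp.intArray(nz + 1)
                ja = glp.intArray(nz + 1)
                ar = glp.doubleArray(nz + 1)
                for k, (i, j, v) in enumerate(entries, start=1):
                    ia[k], ja[k], ar[k] = i, j, v
                glp.glp_load_matrix(lp, nz, ia, ja, ar)
            ret = glp.glp_simplex(lp, self._parm)
            if ret == glp.GLP_ENOPFS:
                return LPResult("infeasible")
            if ret == glp.GLP_ENODFS:
                return LPResult("unbounded")
            if ret != 0:
                return LPResult("error")
            status = glp.glp_get_status(lp)
            if status in (glp.GLP_OPT, glp.GLP_FEAS):
                x = np.array([glp.glp_get_col_prim(lp, j + 1) for j in range(n)])
                return LPResult("optimal", x)
            if status == glp.GLP_NOFEAS:
                return LPResult("infeasible")
            if status == glp.GLP_UNBND:
                return LPResult("unbounded")
            return LPResult("error")
        finally:
            glp.glp_delete_prob(lp)


_BACKENDS: dict[str, object] = {}
_DEFAULT: Optional[str] = None


def get_backend(name: Optional[str] = None):
    """Return a (cached) backend instance; default prefers GLPK."""
    global _DEFAULT
    if name is None:
        if _DEFAULT is None:
            try:
                _BACKENDS.setdefault("glpk", GlpkBackend())
                _DEFAULT = "glpk"
            except ImportError:
                _DEFAULT = "highs"
        name = _DEFAULT
    if name not in _BACKENDS:
        if name == "glpk":
            _BACKENDS[name] = GlpkBackend()
        elif name == "highs":
            _BACKENDS[name] = ScipyHighsBackend()
        else:
            raise ValueError(f"unknown LP backend {name!r}")
    return _BACKENDS[name]


def solve_raw(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None,
              backend=None, counters=None) -> LPResult:
    """Solve one LP; solver errors (not infeasibility) are retried once."""
    be = backend if hasattr(backend, "solve") else get_backend(backend)
    if counters is not None:
        counters["lp_calls"] = counters.get("lp_calls", 0) + 1
    res = be.solve(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if res.status == "error":
        res = be.solve(c, A_ub, b_ub, A_eq, b_eq, bounds)
        if res.status == "error":
            raise BackendError(f"LP backend {be.name!r} failed twice")
    return res


# ---------------------------------------------------------------------------
# Constraint sets and flux vectors
# ---------------------------------------------------------------------------

_CONSTRAINT_RE = re.compile(r"^v(?P<rid>.+?)>=(?P<k>[0-9.eE+-]+)$")


@dataclass(frozen=True)
class ConstraintSet:
    """Search constraints: zero-forced (IFF) and active-forced (FAF) reactions,
    extra flux lower bounds, and basis-column sign assignments for partitioning."""

    iff: frozenset = frozenset()
    faf: frozenset = frozenset()
    flux_bounds: tuple = ()  # ((reaction index, lower bound k >= 0), ...)
    t_signs: tuple = ()      # ((basis column, "inactive" | "active"), ...)

    def __post_init__(self):
        object.__setattr__(self, "iff", frozenset(int(i) for i in self.iff))
        object.__setattr__(self, "faf", frozenset(int(i) for i in self.faf))
        object.__setattr__(self, "flux_bounds",
                           tuple((int(i), float(k)) for i, k in self.flux_bounds))
        object.__setattr__(self, "t_signs",
                           tuple(sorted((int(j), str(s)) for j, s in
                                        (self.t_signs.items() if isinstance(self.t_signs, dict)
                                         else self.t_signs))))
        if self.iff & self.faf:
            raise ValueError(f"iff and faf overlap: {sorted(self.iff & self.faf)}")
        for i, k in self.flux_bounds:
            if k < 0:
                raise ValueError(f"flux bound for reaction {i} is negative ({k})")
        for j, s in self.t_signs:
            if s not in ("inactive", "active"):
                raise ValueError(f"bad t-sign {s!r} for basis column {j}")

    def with_iff(self, *indices: int) -> "ConstraintSet":
        return replace(self, iff=self.iff | set(indices))

    def with_faf(self, *indices: int) -> "ConstraintSet":
        return replace(self, faf=self.faf | set(indices))

    def merged(self, other: "ConstraintSet") -> "ConstraintSet":
        return ConstraintSet(self.iff | other.iff, self.faf | other.faf,
                             self.flux_bounds + other.flux_bounds,
                             self.t_signs + other.t_signs)

    @property
    def t_sign_map(self) -> dict[int, str]:
        return dict(self.t_signs)

    def to_json(self) -> str:
        return json.dumps({"iff": sorted(self.iff), "faf": sorted(self.faf),
                           "flux_bounds": list(self.flux_bounds),
                           "t_signs": list(self.t_signs)})

    @classmethod
    def from_json(cls, text: str) -> "ConstraintSet":
        doc = json.loads(text)
        return cls(frozenset(doc.get("iff", ())), frozenset(doc.get("faf", ())),
                   tuple(tuple(b) for b in doc.get("flux_bounds", ())),
                   tuple(tuple(s) for s in doc.get("t_signs", ())))


def parse_flux_bound(text: str, net) -> tuple[int, float]:
    """Parse a ``vREACTION>=NUMBER`` constraint string against a network."""
    m = _CONSTRAINT_RE.match(text.replace(" ", ""))
    if not m:
        raise ValueError(f"cannot parse constraint {text!r}; expected 'vID>=NUMBER'")
    idx = net.reaction_index(m.group("rid"))
    k = float(m.group("k"))
    if k < 0:
        raise ValueError(f"constraint {text!r} has a negative bound")
    return idx, k


@dataclass
class FluxVector:
    """A nonnegative steady-state flux vector."""

    values: np.ndarray

    def support(self, rtol: float = SUPPORT_ZERO_RTOL) -> np.ndarray:
        return support_of(self.values, rtol)


# ---------------------------------------------------------------------------
# The feasibility test (blank objective) and its derivatives
# ---------------------------------------------------------------------------

def _build_lp(basis: NullspaceBasis, cs: ConstraintSet, force_zero: Optional[int] = None,
              objective: Optional[np.ndarray] = None):
    ns = basis.ns
    r, dof = ns.shape
    lower = np.zeros(r)
    for i in cs.faf:
        lower[i] = max(lower[i], 1.0)
    for i, k in cs.flux_bounds:
        lower[i] = max(lower[i], k)
    zero_rows = set(cs.iff)
    if force_zero is not None:
        zero_rows.add(force_zero)

    a_ub, b_ub, a_eq, b_eq = [], [], [], []
    for i in range(r):
        if i in zero_rows:
            a_eq.append(ns[i])
            b_eq.append(0.0)
        else:
            a_ub.append(-ns[i])
            b_ub.append(-lower[i])

    bounds: list[tuple] = []
    sign_free = set(basis.sign_free_columns) if basis.kind == "efm" else set()
    signs = cs.t_sign_map
    for j in range(dof):
        s = signs.get(j)
        if s == "inactive":
            bounds.append((0.0, 0.0))
        elif s == "active":
            bounds.append((1.0, None))
        elif j in sign_free:
            bounds.append((None, None))
        else:
            bounds.append((0.0, None))
    c = np.zeros(dof) if objective is None else objective
    return (c,
            np.vstack(a_ub) if a_ub else None, np.array(b_ub) if a_ub else None,
            np.vstack(a_eq) if a_eq else None, np.array(b_eq) if a_eq else None,
            bounds)


def feasible(basis: NullspaceBasis, cs: ConstraintSet, backend=None,
             counters=None, force_zero: Optional[int] = None) -> bool:
    """Blank-objective LP feasibility of the constraint configuration."""
    if basis.dof == 0:
        return not cs.faf and not any(k > 0 for _, k in cs.flux_bounds)
    zero_rows = set(cs.iff) | ({force_zero} if force_zero is not None else set())
    if any(k > 0 and i in zero_rows for i, k in cs.flux_bounds):
        return False  # a zero-forced flux cannot meet a positive lower bound
    c, a_ub, b_ub, a_eq, b_eq, bounds = _build_lp(basis, cs, force_zero)
    res = solve_raw(c, a_ub, b_ub, a_eq, b_eq, bounds, backend, counters)
    return res.status in ("optimal", "unbounded")


def forced_active(basis: NullspaceBasis, cs: ConstraintSet,
                  candidates: Iterable[int], backend=None, counters=None,
                  use_min_fva: bool = False) -> set[int]:
    """Reactions among the candidates that cannot carry zero flux under cs.

    The default test adds ``v_i = 0`` per candidate and reports infeasibility
    (half the LP calls of classic min/max FVA); ``use_min_fva`` switches to
    minimizing ``v_i`` and checking that the minimum stays positive.
    """
    out = set()
    for i in candidates:
        if i in cs.faf:
            out.add(i)  # already constrained strictly positive
            continue
        if use_min_fva:
            obj = basis.ns[i].copy()
            c, a_ub, b_ub, a_eq, b_eq, bounds = _build_lp(basis, cs, objective=obj)
            res = solve_raw(c, a_ub, b_ub, a_eq, b_eq, bounds, backend, counters)
            if res.status == "optimal" and float(obj @ res.x) > 1e-9:
                out.add(i)
        elif not feasible(basis, cs, backend, counters, force_zero=i):
            out.add(i)
    return out


def realize(basis: NullspaceBasis, cs: ConstraintSet, backend=None,
            counters=None) -> FluxVector:
    """A concrete flux vector satisfying the constraint set.

    When the iff rows pin DoF-1 independent directions the solution ray is
    unique and the result is normalized to a minimum positive entry of 1.
    """
    if basis.dof == 0:
        raise ValueError("cannot realize a flux vector: DoF is zero")
    # minimizing total flux keeps the solution bounded and vertex-like
    obj = basis.ns.sum(axis=0)
    c, a_ub, b_ub, a_eq, b_eq, bounds = _build_lp(basis, cs, objective=obj)
    res = solve_raw(c, a_ub, b_ub, a_eq, b_eq, bounds, backend, counters)
    if res.status != "optimal":
        raise ValueError(f"constraint set is not realizable (LP {res.status})")
    v = basis.ns @ res.x
    v[np.abs(v) < SUPPORT_ZERO_RTOL * max(1.0, np.max(np.abs(v)))] = 0.0
    pinned = numeric_rank(basis.ns[sorted(cs.iff), :]) if cs.iff else 0
    if pinned == basis.dof - 1:
        v = normalize_flux(v)
    return FluxVector(v)


def max_yield(net, product: str, substrate: str, backend=None) -> float:
    """LP maximum of the product flux with the substrate flux fixed to 1."""
    p = net.reaction_index(product)
    s = net.reaction_index(substrate)
    stoich = net.stoich
    m, r = stoich.shape
    reversible = getattr(net, "reversible", None)
    if reversible is None:
        reversible = net.network.reversible
    bounds = [(None, None) if reversible[j] else (0.0, None) for j in range(r)]
    bounds[s] = (1.0, 1.0)
    c = np.zeros(r)
    c[p] = -1.0
    res = solve_raw(c, A_eq=stoich if m else None, b_eq=np.zeros(m) if m else None,
                    bounds=bounds, backend=backend)
    if res.status == "infeasible":
        raise ValueError(f"no steady-state flux with {substrate!r} fixed to 1")
    if res.status == "unbounded":
        raise ValueError(
            f"maximum of {product!r} is unbounded; the network likely contains "
            "a free cycle producing it")
    if res.status != "optimal":
        raise BackendError("max_yield LP failed")
    return float(res.x[p])
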