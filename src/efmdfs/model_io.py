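"""Metabolic model I/O, reversible splitting, lossless compression and FVA reduction.

A model is a stoichiometric matrix ``S`` (rows = internal metabolites, columns
= reactions) with reversibility flags.  External (boundary) metabolites are
never represented as rows: exchange with the environment shows up as columns
with net production or consumption.

Three dialects are read: a canonical JSON format, a one-reaction-per-line TSV
format, and SBML Level 3 (read-only, via libsbml).  Compression applies three
lossless transformations to an irreversible network — blocked-reaction
removal, enzyme-subset lumping, duplicate-column merging — iterated to a
fixed point, and records an expansion map so that EFMs computed on the
compressed network can be mapped back to the original reaction space.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import EFMRecord, EFMSet, normalize_flux, support_of

#: Large finite cap that stands in for +inf when an LP needs bounded maxima
#: on the (unbounded) flux cone.  Only zero vs nonzero matters downstream.
FLUX_CAP = 1e6

#: A bounded LP optimum below this counts as "cannot carry flux".
BLOCKED_TOL = 1e-9

#: Suffix appended to the backward half of a split reversible reaction.
REV_SUFFIX = "_rev"


class ModelValidationError(ValueError):
    pass


class ModelParseError(ValueError):
    pass


@dataclass
class MetabolicNetwork:
    """Stoichiometric model: S (M x R), reaction/metabolite ids, reversibility."""

    stoich: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    reversible: np.ndarray

    def __post_init__(self):
        self.stoich = np.atleast_2d(np.asarray(self.stoich, dtype=float))
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.validate()

    def validate(self, allow_zero_columns: bool = True):
        m, r = self.stoich.shape
        if len(self.reaction_ids) != r:
            raise ModelValidationError(
                f"{r} stoichiometry columns but {len(self.reaction_ids)} reaction ids")
        if len(self.metabolite_ids) != m:
            raise ModelValidationError(
                f"{m} stoichiometry rows but {len(self.metabolite_ids)} metabolite ids")
        if len(self.reversible) != r:
            raise ModelValidationError("reversible flag vector has wrong length")
        if len(set(self.reaction_ids)) != r:
            dupes = {x for x in self.reaction_ids if self.reaction_ids.count(x) > 1}
            raise ModelValidationError(f"duplicate reaction id(s): {sorted(dupes)}")
        if len(set(self.metabolite_ids)) != m:
            dupes = {x for x in self.metabolite_ids if self.metabolite_ids.count(x) > 1}
            raise ModelValidationError(f"duplicate metabolite id(s): {sorted(dupes)}")
        if not np.isfinite(self.stoich).all():
            raise ModelValidationError("stoichiometric coefficients must be finite")
        if not allow_zero_columns and m > 0:
            zero = ~np.any(self.stoich != 0.0, axis=0)
            if zero.any():
                bad = [self.reaction_ids[i] for i in np.flatnonzero(zero)]
                raise ModelValidationError(f"all-zero stoichiometry column(s): {bad}")

    @property
    def n_metabolites(self) -> int:
        return self.stoich.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(self.stoich.copy(), list(self.reaction_ids),
                                list(self.metabolite_ids), self.reversible.copy())

    def drop_zero_columns(self) -> "MetabolicNetwork":
        """Return a copy without all-zero columns, warning if any were dropped."""
        if self.n_metabolites == 0:
            return self.copy()
        keep = np.any(self.stoich != 0.0, axis=0)
        if keep.all():
            return self.copy()
        dropped = [self.reaction_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping all-zero stoichiometry column(s): {dropped}")
        return MetabolicNetwork(self.stoich[:, keep],
                                [r for r, k in zip(self.reaction_ids, keep) if k],
                                list(self.metabolite_ids), self.reversible[keep])


@dataclass
class IrreversibleNetwork:
    """A network whose reversible reactions have been split into forward/backward pairs."""

    base: MetabolicNetwork
    split_map: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.base.reversible.any():
            raise ModelValidationError("IrreversibleNetwork base must have no reversible flags")

    @property
    def network(self) -> MetabolicNetwork:
        return self.base

    @property
    def stoich(self) -> np.ndarray:
        return self.base.stoich

    @property
    def reaction_ids(self) -> list[str]:
        return self.base.reaction_ids

    @property
    def metabolite_ids(self) -> list[str]:
        return self.base.metabolite_ids

    @property
    def n_reactions(self) -> int:
        return self.base.n_reactions

    def reaction_index(self, rid: str) -> int:
        return self.base.reaction_index(rid)


def as_irreversible(net) -> IrreversibleNetwork:
    """Coerce to IrreversibleNetwork, splitting reversible reactions if needed."""
    if isinstance(net, IrreversibleNetwork):
        return net
    if net.reversible.any():
        return split_reversible(net)
    return IrreversibleNetwork(net.copy())


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

EXTERNAL_PREFIX = "x_"


def read_network(path, format: Optional[str] = None) -> MetabolicNetwork:
    """Read a model from JSON, TSV or SBML.

    The dialect is inferred from the file suffix when ``format`` is None.
    All-zero stoichiometry columns are dropped with a warning.
    """
    path = str(path)
    if format is None:
        suffix = path.rsplit(".", 1)[-1].lower()
        format = {"json": "json", "tsv": "tsv", "txt": "tsv",
                  "xml": "sbml", "sbml": "sbml"}.get(suffix)
        if format is None:
            raise ModelParseError(f"cannot infer model format from path {path!r}")
    if format == "json":
        net = _read_json(path)
    elif format == "tsv":
        net = _read_tsv(path)
    elif format == "sbml":
        net = _read_sbml(path)
    else:
        raise ModelParseError(f"unknown model format {format!r}")
    return net.drop_zero_columns()


def _read_json(path) -> MetabolicNetwork:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelParseError(f"{path}: invalid JSON: {exc}") from exc
    try:
        mets = doc["metabolites"]
        rxns = doc["reactions"]
    except (KeyError, TypeError) as exc:
        raise ModelParseError(f"{path}: expected 'metabolites' and 'reactions' keys") from exc
    internal = [m["id"] for m in mets if not m.get("external", False)]
    external = {m["id"] for m in mets if m.get("external", False)}
    row = {mid: i for i, mid in enumerate(internal)}
    reaction_ids, reversible = [], []
    stoich = np.zeros((len(internal), len(rxns)))
    for j, rx in enumerate(rxns):
        reaction_ids.append(str(rx["id"]))
        reversible.append(bool(rx.get("reversible", False)))
        for mid, coef in rx.get("stoich", {}).items():
            if not isinstance(coef, (int, float)) or not math.isfinite(coef):
                raise ModelValidationError(
                    f"{path}: reaction {rx['id']!r}: non-finite coefficient for {mid!r}")
            if mid in external:
                continue
            if mid not in row:
                raise ModelValidationError(
                    f"{path}: reaction {rx['id']!r} references undeclared metabolite {mid!r}")
            stoich[row[mid], j] = coef
    return MetabolicNetwork(stoich, reaction_ids, internal, np.array(reversible, dtype=bool))


def _parse_equation_side(text: str, lineno: int):
    terms = []
    text = text.strip()
    if not text:
        return terms
    for chunk in text.split("+"):
        parts = chunk.split()
        if len(parts) == 1:
            coef, met = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError:
                raise ModelParseError(
                    f"line {lineno}: bad stoichiometric coefficient {parts[0]!r}") from None
            met = parts[1]
        else:
            raise ModelParseError(f"line {lineno}: malformed term {chunk.strip()!r}")
        if not math.isfinite(coef):
            raise ModelValidationError(f"line {lineno}: non-finite coefficient")
        terms.append((met, coef))
    return terms


def _read_tsv(path) -> MetabolicNetwork:
    reaction_ids, reversible, equations = [], [], []
    met_order: list[str] = []
    seen_mets: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ModelParseError(
                    f"line {lineno}: expected 'id<TAB>equation<TAB>R|I', got {line!r}")
            rid, eqn, revflag = fields
            if revflag not in ("R", "I"):
                raise ModelParseError(f"line {lineno}: reversibility must be 'R' or 'I'")
            if "->" not in eqn:
                raise ModelParseError(f"line {lineno}: missing '->' in equation {eqn!r}")
            lhs_text, rhs_text = eqn.split("->", 1)
            lhs = _parse_equation_side(lhs_text, lineno)
            rhs = _parse_equation_side(rhs_text, lineno)
            reaction_ids.append(rid.strip())
            reversible.append(revflag == "R")
            equations.append((lhs, rhs))
            for met, _ in lhs + rhs:
                if not met.startswith(EXTERNAL_PREFIX) and met not in seen_mets:
                    seen_mets.add(met)
                    met_order.append(met)
    row = {mid: i for i, mid in enumerate(met_order)}
    stoich = np.zeros((len(met_order), len(reaction_ids)))
    for j, (lhs, rhs) in enumerate(equations):
        for met, coef in lhs:
            if met in row:
                stoich[row[met], j] -= coef
        for met, coef in rhs:
            if met in row:
                stoich[row[met], j] += coef
    return MetabolicNetwork(stoich, reaction_ids, met_order, np.array(reversible, dtype=bool))


def _read_sbml(path) -> MetabolicNetwork:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelParseError(f"{path}: SBML error: {err.getMessage() if err else 'unreadable'}")
    model = doc.getModel()
    if model is None:
        raise ModelParseError(f"{path}: no SBML model element")
    internal, external = [], set()
    for sp in model.getListOfSpecies():
        if sp.getBoundaryCondition():
            external.add(sp.getId())
        else:
            internal.append(sp.getId())
    row = {mid: i for i, mid in enumerate(internal)}
    n_rxn = model.getNumReactions()
    stoich = np.zeros((len(internal), n_rxn))
    reaction_ids, reversible = [], []
    for j in range(n_rxn):
        rx = model.getReaction(j)
        reaction_ids.append(rx.getId())
        reversible.append(bool(rx.getReversible()))
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            mid = ref.getSpecies()
            if mid in row:
                stoich[row[mid], j] -= ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            mid = ref.getSpecies()
            if mid in row:
                stoich[row[mid], j] += ref.getStoichiometry()
    return MetabolicNetwork(stoich, reaction_ids, internal, np.array(reversible, dtype=bool))


def write_network(net: MetabolicNetwork, path, format: str = "json") -> None:
    path = str(path)
    if format == "json":
        doc = {
            "metabolites": [{"id": m, "external": False} for m in net.metabolite_ids],
            "reactions": [
                {
                    "id": rid,
                    "stoich": {net.metabolite_ids[i]: float(net.stoich[i, j])
                               for i in np.flatnonzero(net.stoich[:, j])},
                    "reversible": bool(net.reversible[j]),
                }
                for j, rid in enumerate(net.reaction_ids)
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            for j, rid in enumerate(net.reaction_ids):
                lhs, rhs = [], []
                for i in np.flatnonzero(net.stoich[:, j]):
                    coef = net.stoich[i, j]
                    term = (f"{abs(coef):g} {net.metabolite_ids[i]}"
                            if abs(coef) != 1 else net.metabolite_ids[i])
                    (rhs if coef > 0 else lhs).append(term)
                eqn = f"{' + '.join(lhs)} -> {' + '.join(rhs)}"
                flag = "R" if net.reversible[j] else "I"
                fh.write(f"{rid}\t{eqn}\t{flag}\n")
    else:
        raise ValueError(f"unsupported output format {format!r}")


# ---------------------------------------------------------------------------
# Reversible splitting
# ---------------------------------------------------------------------------

def split_reversible(net: MetabolicNetwork) -> IrreversibleNetwork:
    """Decompose every reversible reaction into an opposing irreversible pair.

    Forward columns keep their position and id; backward columns (negated
    stoichiometry, id suffixed with ``_rev``) are appended in original order.
    """
    rev_idx = np.flatnonzero(net.reversible)
    cols = [net.stoich]
    ids = list(net.reaction_ids)
    split_map: dict[str, tuple[str, str]] = {}
    for j in rev_idx:
        fwd_id = net.reaction_ids[j]
        bwd_id = fwd_id + REV_SUFFIX
        while bwd_id in ids:
            bwd_id += "_"
        ids.append(bwd_id)
        cols.append(-net.stoich[:, [j]])
        split_map[fwd_id] = (fwd_id, bwd_id)
    stoich = np.hstack(cols) if len(cols) > 1 else net.stoich.copy()
    base = MetabolicNetwork(stoich, ids, list(net.metabolite_ids),
                            np.zeros(len(ids), dtype=bool))
    return IrreversibleNetwork(base, split_map)


def merge_split_pairs(inet: IrreversibleNetwork) -> MetabolicNetwork:
    """Inverse of :func:`split_reversible` (used to round-trip-check the split)."""
    base = inet.base
    drop = set()
    reversible = []
    keep_ids = []
    cols = []
    bwd_ids = {b for _, b in inet.split_map.values()}
    for j, rid in enumerate(base.reaction_ids):
        if rid in bwd_ids:
            drop.add(j)
    for j, rid in enumerate(base.reaction_ids):
        if j in drop:
            continue
        keep_ids.append(rid)
        cols.append(base.stoich[:, j])
        reversible.append(rid in inet.split_map)
    return MetabolicNetwork(np.column_stack(cols), keep_ids,
                            list(base.metabolite_ids), np.array(reversible, dtype=bool))


# ---------------------------------------------------------------------------
# Compression
# ---------------------------------------------------------------------------

# Expansion trees: ("leaf", rid) | ("and", [(tree, ratio), ...]) | ("or", [(tree, ratio), ...])
# A unit flux on the compressed column expands to flux `ratio` on each AND child,
# or to flux `ratio` on exactly one OR child (one original EFM per choice).


def _tree_alternatives(tree) -> list[dict[str, float]]:
    kind = tree[0]
    if kind == "leaf":
        return [{tree[1]: 1.0}]
    if kind == "and":
        alts = [{}]
        for child, ratio in tree[1]:
            child_alts = _tree_alternatives(child)
            new = []
            for base in alts:
                for ca in child_alts:
                    d = dict(base)
                    for k, v in ca.items():
                        d[k] = v * ratio
                    new.append(d)
            alts = new
        return alts
    if kind == "or":
        out = []
        for child, ratio in tree[1]:
            for ca in _tree_alternatives(child):
                out.append({k: v * ratio for k, v in ca.items()})
        return out
    raise ValueError(f"bad expansion tree node {kind!r}")


def _tree_leaves(tree) -> list[tuple[str, float]]:
    """All leaves with path-product ratios (within their own OR alternative)."""
    kind = tree[0]
    if kind == "leaf":
        return [(tree[1], 1.0)]
    leaves = []
    for child, ratio in tree[1]:
        leaves.extend((rid, r * ratio) for rid, r in _tree_leaves(child))
    return leaves


def _tree_has_or(tree) -> bool:
    if tree[0] == "leaf":
        return False
    if tree[0] == "or":
        return True
    return any(_tree_has_or(c) for c, _ in tree[1])


@dataclass
class CompressionGroup:
    compressed_id: str
    members: list[tuple[str, float]]
    kind: str  # "subset" (fixed-ratio lump) or "choice" (duplicate merge)


@dataclass
class CompressionMap:
    """Mapping from a compressed network back to original reaction space."""

    original_reaction_ids: list[str]
    compressed_reaction_ids: list[str]
    trees: list  # one expansion tree per compressed column
    dropped: list[str]

    @property
    def groups(self) -> list[CompressionGroup]:
        out = []
        for cid, tree in zip(self.compressed_reaction_ids, self.trees):
            kind = "choice" if _tree_has_or(tree) else "subset"
            out.append(CompressionGroup(cid, _tree_leaves(tree), kind))
        return out

    def to_json(self) -> str:
        return json.dumps({
            "original_reaction_ids": self.original_reaction_ids,
            "compressed_reaction_ids": self.compressed_reaction_ids,
            "trees": self.trees,
            "dropped": self.dropped,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CompressionMap":
        doc = json.loads(text)

        def fix(node):
            if node[0] == "leaf":
                return ("leaf", node[1])
            return (node[0], [(fix(c), float(r)) for c, r in node[1]])

        return cls(doc["original_reaction_ids"], doc["compressed_reaction_ids"],
                   [fix(t) for t in doc["trees"]], doc["dropped"])


def _max_flux(stoich: np.ndarray, j: int, extra_rows=None) -> float:
    """Bounded LP maximum of v_j over {S v = 0, 0 <= v <= FLUX_CAP}."""
    from . import lp_engine

    m, r = stoich.shape
    c = np.zeros(r)
    c[j] = -1.0
    bounds = [(0.0, FLUX_CAP)] * r
    a_ub, b_ub = extra_rows if extra_rows else (None, None)
    res = lp_engine.solve_raw(c, A_eq=stoich if m else None,
                              b_eq=np.zeros(m) if m else None,
                              A_ub=a_ub, b_ub=b_ub, bounds=bounds)
    if res.status != "optimal":
        return 0.0
    return float(res.x[j])


def compress(net, constraints=None, lump_subsets: bool = True):
    """Losslessly compress an irreversible network.

    Iterates to a fixed point over: (a) removal of blocked reactions (zero
    bounded-LP maximum), (b) lumping of enzyme subsets (reactions whose
    fluxes hold a fixed strictly positive ratio in every steady state,
    detected from proportional rows of a nullspace basis), (c) merging of
    duplicate columns, (d) dropping of all-zero metabolite rows.  Returns
    ``(compressed_network, CompressionMap)``; EFM sets before and after
    correspond under :func:`expand_efms`.

    ``constraints`` (optional): IFF members are treated as blocked up front;
    FAF members and flux lower bounds participate in the blocked-reaction LPs
    while their reactions survive unmerged.
    """
    from scipy.linalg import null_space

    inet = net if isinstance(net, IrreversibleNetwork) else None
    base = inet.network if inet else net
    if base.reversible.any():
        raise ModelValidationError("compress requires an irreversible network")

    stoich = base.stoich.copy()
    ids = list(base.reaction_ids)
    mets = list(base.metabolite_ids)
    trees = [("leaf", rid) for rid in ids]
    dropped: list[str] = []

    cs_iff_ids: set[str] = set()
    cs_faf_ids: set[str] = set()
    cs_bounds: dict[str, float] = {}
    if constraints is not None:
        cs_iff_ids = {base.reaction_ids[i] for i in constraints.iff}
        cs_faf_ids = {base.reaction_ids[i] for i in constraints.faf}
        for i, k in constraints.flux_bounds:
            cs_bounds[base.reaction_ids[i]] = max(cs_bounds.get(base.reaction_ids[i], 0.0), k)

    def drop_columns(kill: set[int]):
        nonlocal stoich, ids, trees
        for j in sorted(kill):
            dropped.extend(rid for rid, _ in _tree_leaves(trees[j]))
        keep = [j for j in range(len(ids)) if j not in kill]
        stoich = stoich[:, keep]
        ids = [ids[j] for j in keep]
        trees = [trees[j] for j in keep]

    # constraint-forced zeros are blocked by definition
    if cs_iff_ids:
        drop_columns({j for j, rid in enumerate(ids) if rid in cs_iff_ids})

    while True:
        changed = False

        # (a) blocked reactions
        extra = None
        lb_rows = []
        lb_vals = []
        for rid in (cs_faf_ids | set(cs_bounds)):
            if rid in ids:
                row = np.zeros(len(ids))
                row[ids.index(rid)] = -1.0
                lb_rows.append(row)
                lb_vals.append(-max(1.0 if rid in cs_faf_ids else 0.0,
                                    cs_bounds.get(rid, 0.0)))
        if lb_rows:
            extra = (np.vstack(lb_rows), np.array(lb_vals))
        blocked = {j for j in range(len(ids))
                   if _max_flux(stoich, j, extra) < BLOCKED_TOL}
        if blocked:
            drop_columns(blocked)
            changed = True

        # (d) all-zero metabolite rows
        if stoich.shape[0] and len(ids):
            live = np.any(np.abs(stoich) > 1e-9, axis=1)
            if not live.all():
                stoich = stoich[live, :]
                mets = [m for m, keep in zip(mets, live) if keep]
                changed = True

        if not len(ids):
            break

        # (b) enzyme subsets: proportional rows of a nullspace basis
        if lump_subsets:
            ns = null_space(stoich) if stoich.shape[0] else np.eye(len(ids))
            if ns.shape[1] == 0:
                drop_columns(set(range(len(ids))))
                break
            norms = np.linalg.norm(ns, axis=1)
            grouped: set[int] = set()
            merges = []
            for i in range(len(ids)):
                if i in grouped or norms[i] < 1e-12:
                    continue
                members = [(i, 1.0)]
                for j in range(i + 1, len(ids)):
                    if j in grouped or norms[j] < 1e-12:
                        continue
                    dot = float(ns[i] @ ns[j])
                    if dot <= 0:
                        continue
                    cos = dot / (norms[i] * norms[j])
                    if abs(cos - 1.0) < 1e-9:
                        members.append((j, norms[j] / norms[i]))
                        grouped.add(j)
                if len(members) > 1:
                    grouped.update(j for j, _ in members)
                    merges.append(members)
            if merges:
                kill = set()
                for members in merges:
                    rep = members[0][0]
                    new_col = sum(ratio * stoich[:, j] for j, ratio in members)
                    new_col[np.abs(new_col) < 1e-9] = 0.0  # cancel float residue
                    stoich[:, rep] = new_col
                    trees[rep] = ("and", [(trees[j], ratio) for j, ratio in members])
                    kill.update(j for j, _ in members[1:])
                drop_keep = [j for j in range(len(ids)) if j not in kill]
                stoich = stoich[:, drop_keep]
                ids = [ids[j] for j in drop_keep]
                trees = [trees[j] for j in drop_keep]
                changed = True

        # (c) duplicate columns (equal up to a positive factor): OR-merge
        if len(ids) > 1:
            colnorm = np.linalg.norm(stoich, axis=0)
            merged: set[int] = set()
            any_dup = False
            new_cols, new_ids, new_trees = [], [], []
            for i in range(len(ids)):
                if i in merged:
                    continue
                alts = [(trees[i], 1.0)]
                for j in range(i + 1, len(ids)):
                    if j in merged:
                        continue
                    if colnorm[i] < 1e-12 and colnorm[j] < 1e-12:
                        same = True
                        factor = 1.0
                    elif colnorm[i] < 1e-12 or colnorm[j] < 1e-12:
                        continue
                    else:
                        dot = float(stoich[:, i] @ stoich[:, j])
                        if dot <= 0:
                            continue
                        if abs(dot / (colnorm[i] * colnorm[j]) - 1.0) >= 1e-9:
                            continue
                        same = True
                        factor = colnorm[j] / colnorm[i]  # col_j = factor * col_i
                    if same:
                        # unit flux on kept column i == flux 1/factor on member j
                        alts.append((trees[j], 1.0 / factor))
                        merged.add(j)
                        any_dup = True
                new_cols.append(stoich[:, i])
                new_ids.append(ids[i])
                new_trees.append(("or", alts) if len(alts) > 1 else alts[0][0])
            if any_dup:
                stoich = np.column_stack(new_cols) if new_cols else stoich[:, :0]
                ids, trees = new_ids, new_trees
                changed = True

        if not changed:
            break

    compressed = MetabolicNetwork(stoich, ids, mets, np.zeros(len(ids), dtype=bool))
    cmap = CompressionMap(list(base.reaction_ids), ids, trees, dropped)
    return compressed, cmap


def expand_efms(efms: EFMSet, cmap: CompressionMap) -> EFMSet:
    """Map EFMs of a compressed network back to original reaction space.

    Fixed-ratio (subset) groups expand deterministically; duplicate-merge
    (choice) groups expand one compressed EFM into one original EFM per
    combination of member choices.  Dropped reactions carry zero flux.
    """
    if len(efms.reaction_ids) != len(cmap.compressed_reaction_ids):
        raise ValueError(
            f"EFM set has {len(efms.reaction_ids)} reactions but the compression map "
            f"describes {len(cmap.compressed_reaction_ids)}")
    orig_index = {rid: i for i, rid in enumerate(cmap.original_reaction_ids)}
    n_orig = len(cmap.original_reaction_ids)
    out = EFMSet(list(cmap.original_reaction_ids))
    for rec in efms:
        active = np.flatnonzero(rec.support)
        partials = [np.zeros(n_orig)]
        for j in active:
            flux_j = rec.flux[j]
            alternatives = _tree_alternatives(cmap.trees[j])
            new_partials = []
            for base_vec in partials:
                for alt in alternatives:
                    vec = base_vec.copy()
                    for rid, ratio in alt.items():
                        vec[orig_index[rid]] += flux_j * ratio
                    new_partials.append(vec)
            partials = new_partials
        for vec in partials:
            flux = normalize_flux(vec)
            out.add(EFMRecord(support_of(flux), flux))
    return out


# ---------------------------------------------------------------------------
# FVA reduction and drain replacement
# ---------------------------------------------------------------------------

def fva_reduce(net: MetabolicNetwork, objective_reaction: str,
               fixed_uptake: str) -> MetabolicNetwork:
    """Keep only reactions that can carry flux at the maximum objective yield.

    With the uptake flux fixed to one unit, the objective flux is maximized
    by LP and then pinned to that maximum; flux variability analysis (a
    min/max LP per reaction) retains exactly the reactions whose flux range
    is not identically zero.
    """
    from . import lp_engine

    obj = net.reaction_index(objective_reaction)
    upt = net.reaction_index(fixed_uptake)
    m, r = net.stoich.shape
    bounds = [(-FLUX_CAP, FLUX_CAP) if net.reversible[j] else (0.0, FLUX_CAP)
              for j in range(r)]
    bounds[upt] = (1.0, 1.0)
    c = np.zeros(r)
    c[obj] = -1.0
    res = lp_engine.solve_raw(c, A_eq=net.stoich, b_eq=np.zeros(m), bounds=bounds)
    if res.status == "infeasible":
        raise ValueError(f"objective LP infeasible with {fixed_uptake!r} fixed to 1")
    if res.status != "optimal":
        raise ValueError(f"objective LP failed: {res.status}")
    vmax = float(res.x[obj])
    if vmax >= FLUX_CAP * (1 - 1e-6):
        raise ValueError("objective LP unbounded (hit internal flux cap); "
                         "check for a free cycle through the objective")
    if vmax <= BLOCKED_TOL:
        raise ValueError("objective maximum is not positive")

    bounds[obj] = (vmax, vmax)
    keep = np.zeros(r, dtype=bool)
    keep[[obj, upt]] = True
    for j in range(r):
        if keep[j]:
            continue
        for sense in (-1.0, 1.0):
            cj = np.zeros(r)
            cj[j] = sense
            rj = lp_engine.solve_raw(cj, A_eq=net.stoich, b_eq=np.zeros(m), bounds=bounds)
            if rj.status == "optimal" and abs(rj.x[j]) > BLOCKED_TOL:
                keep[j] = True
                break
    sub = MetabolicNetwork(net.stoich[:, keep],
                           [rid for rid, k in zip(net.reaction_ids, keep) if k],
                           list(net.metabolite_ids), net.reversible[keep])
    live = np.any(sub.stoich != 0.0, axis=1) if sub.n_metabolites else np.array([], dtype=bool)
    if sub.n_metabolites and not live.all():
        sub = MetabolicNetwork(sub.stoich[live, :], sub.reaction_ids,
                               [mid for mid, k in zip(sub.metabolite_ids, live) if k],
                               sub.reversible)
    return sub


def replace_with_drains(net: MetabolicNetwork, reaction: str) -> MetabolicNetwork:
    """Replace one composite reaction by per-metabolite unit drains/sources.

    Each internal metabolite the reaction consumed gets a unit drain column
    and each it produced gets a unit source column.  Used to decompose a
    single lumped biomass equation into individual component drains so that
    sub-models can select which components must be producible.
    """
    j = net.reaction_index(reaction)
    col = net.stoich[:, j]
    consumed = np.flatnonzero(col < 0)
    produced = np.flatnonzero(col > 0)
    if consumed.size == 0:
        raise ValueError(f"reaction {reaction!r} consumes no internal metabolite")
    keep = [k for k in range(net.n_reactions) if k != j]
    cols = [net.stoich[:, keep]]
    ids = [net.reaction_ids[k] for k in keep]
    reversible = list(net.reversible[keep])
    existing = set(ids)

    def fresh(name):
        while name in existing:
            name += "_"
        existing.add(name)
        return name

    for i in consumed:
        c = np.zeros((net.n_metabolites, 1))
        c[i, 0] = -1.0
        cols.append(c)
        ids.append(fresh(f"drain_{net.metabolite_ids[i]}"))
        reversible.append(False)
    for i in produced:
        c = np.zeros((net.n_metabolites, 1))
        c[i, 0] = 1.0
        cols.append(c)
        ids.append(fresh(f"source_{net.metabolite_ids[i]}"))
        reversible.append(False)
    return MetabolicNetwork(np.hstack(cols), ids, list(net.metabolite_ids),
                            np.array(reversible, dtype=bool))
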