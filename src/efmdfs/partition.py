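"""Divide-and-conquer partitioning of an EFM enumeration into exclusive sub-jobs.

Fixing the participation of k nullspace basis vectors — each coefficient
``t_j`` forced either to zero ("inactive") or to at least one ("active") —
splits the flux cone into 2^k exclusive subspaces that can be searched
independently, on as many machines as available, with no coordination.  For
the rref basis, column j's coefficient equals the flux of pivot reaction j,
so the jobs partition the EFMs by the activity pattern of the chosen pivot
reactions; for a sparse-EFM basis only the sign-free columns are offered by
default.  Merging concatenates the per-job outputs and verifies that no
support appears twice.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from itertools import product
from typing import Optional

import numpy as np

from .dfs_search import enumerate_efms
from .lp_engine import ConstraintSet
from .nullspace_core import NullspaceBasis
from .records import EFMRecord, EFMSet, support_of

MAX_SPLIT_COLUMNS = 20


@dataclass
class JobDescriptor:
    """One exclusive sub-job: a full inactive/active assignment of the chosen columns."""

    job_id: str
    t_signs: dict[int, str]
    extra_constraints: ConstraintSet = field(default_factory=ConstraintSet)
    basis_kind: str = "rref"

    def constraint_set(self) -> ConstraintSet:
        return ConstraintSet(self.extra_constraints.iff, self.extra_constraints.faf,
                             self.extra_constraints.flux_bounds,
                             tuple(sorted(self.t_signs.items())))

    def to_json(self) -> str:
        return json.dumps({"job_id": self.job_id,
                           "t_signs": {str(k): v for k, v in self.t_signs.items()},
                           "extra_constraints": json.loads(self.extra_constraints.to_json()),
                           "basis_kind": self.basis_kind}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "JobDescriptor":
        doc = json.loads(text)
        return cls(doc["job_id"],
                   {int(k): v for k, v in doc["t_signs"].items()},
                   ConstraintSet.from_json(json.dumps(doc.get("extra_constraints", {}))),
                   doc.get("basis_kind", "rref"))


def make_jobs(basis: NullspaceBasis, columns: list[int],
              extra_constraints: Optional[ConstraintSet] = None) -> list[JobDescriptor]:
    """All 2^k inactive/active assignments of the chosen basis columns."""
    columns = list(columns)
    if len(set(columns)) != len(columns):
        raise ValueError("split columns must be distinct")
    if len(columns) > MAX_SPLIT_COLUMNS:
        raise ValueError(
            f"refusing to create 2^{len(columns)} jobs (limit 2^{MAX_SPLIT_COLUMNS})")
    if any(j < 0 or j >= basis.dof for j in columns):
        raise ValueError(f"split column out of range 0..{basis.dof - 1}")
    if basis.kind == "efm":
        allowed = set(basis.sign_free_columns) | set(basis.pivot_rows)
        bad = [j for j in columns if j not in allowed]
        if bad:
            raise ValueError(
                f"efm-basis split columns must be sign-free columns: {bad}")
    extra = extra_constraints or ConstraintSet()
    jobs = []
    for bits in product(("inactive", "active"), repeat=len(columns)):
        tag = "".join("1" if b == "active" else "0" for b in bits)
        jobs.append(JobDescriptor(f"job_{tag or 'all'}",
                                  dict(zip(columns, bits)), extra, basis.kind))
    return jobs


def run_job(net, job: JobDescriptor, sink=None, backend=None,
            check_duplicates: bool = False) -> EFMSet:
    """Enumerate the EFMs of one sub-job; output is tagged with the job id."""
    res = enumerate_efms(net, job.constraint_set(), basis_kind=job.basis_kind,
                         backend=backend, sink=sink,
                         check_duplicates=check_duplicates)
    efms = res.efms
    efms.job_id = job.job_id
    return efms


@dataclass
class MergeResult:
    efms: EFMSet
    per_job_counts: dict[str, int]


def merge(parts: list[EFMSet]) -> MergeResult:
    """Concatenate sub-job outputs, enforcing pairwise support disjointness."""
    if not parts:
        raise ValueError("nothing to merge")
    out = EFMSet(list(parts[0].reaction_ids))
    counts: dict[str, int] = {}
    for k, part in enumerate(parts):
        if part.reaction_ids != out.reaction_ids:
            raise ValueError("sub-job outputs disagree on the reaction list")
        job_id = part.job_id or f"part_{k}"
        counts[job_id] = len(part)
        for rec in part:
            try:
                out.add(rec)
            except ValueError:
                raise ValueError(
                    f"duplicate EFM support across sub-jobs (in {job_id}): "
                    f"{np.flatnonzero(rec.support).tolist()}; "
                    "sub-jobs are expected to be exclusive") from None
    return MergeResult(out, counts)


# ---------------------------------------------------------------------------
# jobs/ directory convention
# ---------------------------------------------------------------------------

def write_jobs(directory, jobs: list[JobDescriptor], columns: list[int],
               model_path: Optional[str] = None) -> None:
    """One JSON descriptor per job plus a manifest describing the split."""
    os.makedirs(directory, exist_ok=True)
    for job in jobs:
        with open(os.path.join(directory, f"{job.job_id}.json"), "w") as fh:
            fh.write(job.to_json())
    manifest = {"columns": list(map(int, columns)),
                "jobs": [job.job_id for job in jobs],
                "basis_kind": jobs[0].basis_kind if jobs else "rref",
                "model": model_path}
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_manifest(directory) -> dict:
    with open(os.path.join(directory, "manifest.json")) as fh:
        return json.load(fh)


def read_job(directory, job_id: str) -> JobDescriptor:
    with open(os.path.join(directory, f"{job_id}.json")) as fh:
        return JobDescriptor.from_json(fh.read())


def write_job_output(directory, efms: EFMSet) -> None:
    doc = {"job_id": efms.job_id, "reaction_ids": efms.reaction_ids,
           "efms": [{"flux": rec.flux.tolist(),
                     "iff_set": sorted(rec.iff_set)} for rec in efms]}
    with open(os.path.join(directory, f"{efms.job_id}_efms.json"), "w") as fh:
        json.dump(doc, fh)


def read_job_output(directory, job_id: str) -> EFMSet:
    with open(os.path.join(directory, f"{job_id}_efms.json")) as fh:
        doc = json.load(fh)
    out = EFMSet(doc["reaction_ids"], job_id=doc["job_id"])
    for item in doc["efms"]:
        flux = np.asarray(item["flux"], dtype=float)
        out.add(EFMRecord(support_of(flux), flux, frozenset(item["iff_set"])))
    return out
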