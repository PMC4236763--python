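"""Containers for enumerated elementary flux modes.

An elementary flux mode (EFM) is a support-minimal nonzero steady-state flux
vector of an irreversible network, unique up to positive scaling.  Throughout
the package EFMs are normalized so that their smallest strictly positive flux
entry equals one, which makes support sets and flux vectors directly
comparable between the depth-first search, the brute-force oracle and any
partitioned sub-job output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

#: Relative tolerance below which a flux entry counts as zero when a support
#: is extracted from a numeric flux vector.
SUPPORT_ZERO_RTOL = 1e-9


def support_of(values: np.ndarray, rtol: float = SUPPORT_ZERO_RTOL) -> np.ndarray:
    """Boolean support of a flux vector under the relative zero tolerance."""
    values = np.asarray(values, dtype=float)
    scale = np.max(np.abs(values)) if values.size else 0.0
    if scale == 0.0:
        return np.zeros(values.shape, dtype=bool)
    return np.abs(values) > rtol * scale


def normalize_flux(values: np.ndarray, rtol: float = SUPPORT_ZERO_RTOL) -> np.ndarray:
    """Scale a nonnegative flux vector so its minimum positive entry is 1.

    Entries below the relative zero tolerance are snapped to exactly zero.
    """
    values = np.asarray(values, dtype=float).copy()
    supp = support_of(values, rtol)
    values[~supp] = 0.0
    if supp.any():
        values /= np.min(values[supp])
    return values


@dataclass(frozen=True)
class EFMRecord:
    """One elementary flux mode.

    Attributes
    ----------
    support:
        Boolean vector of length R; True where the mode carries flux.
    flux:
        Nonnegative flux values, min positive entry normalized to 1.
    iff_set:
        The leading DoF-1 inactive free fluxes that uniquely identify the
        mode in the depth-first search (empty for oracle output when not
        computed).
    """

    support: np.ndarray
    flux: np.ndarray
    iff_set: frozenset = frozenset()

    def support_key(self) -> bytes:
        return np.packbits(self.support.astype(np.uint8)).tobytes()

    def __eq__(self, other) -> bool:  # support defines identity
        if not isinstance(other, EFMRecord):
            return NotImplemented
        return bool(np.array_equal(self.support, other.support))

    def __hash__(self) -> int:
        return hash(self.support_key())


class EFMSet:
    """A collection of EFMs over a fixed reaction list.

    Deduplicates by support; iteration order is insertion order.
    """

    def __init__(self, reaction_ids: list[str], records: Optional[Iterable[EFMRecord]] = None,
                 job_id: Optional[str] = None):
        self.reaction_ids = list(reaction_ids)
        self.job_id = job_id
        self._records: list[EFMRecord] = []
        self._keys: set[bytes] = set()
        for rec in records or ():
            self.add(rec)

    def add(self, rec: EFMRecord, *, allow_duplicate: bool = False) -> bool:
        """Add a record; returns False (and skips) on a duplicate support."""
        key = rec.support_key()
        if key in self._keys:
            if allow_duplicate:
                return False
            raise ValueError("duplicate EFM support added to EFMSet")
        self._keys.add(key)
        self._records.append(rec)
        return True

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[EFMRecord]:
        return iter(self._records)

    def __contains__(self, rec: EFMRecord) -> bool:
        return rec.support_key() in self._keys

    @property
    def records(self) -> list[EFMRecord]:
        return list(self._records)

    def support_matrix(self) -> np.ndarray:
        """Binary support matrix, rows = EFMs, columns = reactions."""
        if not self._records:
            return np.zeros((0, len(self.reaction_ids)), dtype=np.int8)
        return np.vstack([r.support.astype(np.int8) for r in self._records])

    def flux_matrix(self) -> np.ndarray:
        if not self._records:
            return np.zeros((0, len(self.reaction_ids)))
        return np.vstack([r.flux for r in self._records])

    def support_keys(self) -> set[bytes]:
        return set(self._keys)

    def same_supports(self, other: "EFMSet") -> bool:
        """Set equality of supports, ignoring order and flux scaling."""
        return self.support_keys() == other.support_keys()
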