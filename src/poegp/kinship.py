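"""Pedigree relationship algebra.

Builds the numerator relationship matrix ``A`` (expected additive genetic
covariance among individuals), the gametic relationship matrix ``L``
(expected covariance among the paternal and maternal gametes of all
individuals) and the individual-to-gamete incidence matrix ``M``.  The three
satisfy the identity ``0.5 * M @ L @ M.T == A`` exactly, which is the main
internal consistency check of this module.

Conventions
-----------
* Pedigree records are topologically ordered (parents before offspring).
* Unknown parents are treated as unrelated, non-inbred draws from the base
  population (the standard tabular-method convention).
* Gamete rows are ordered ``(paternal, maternal)`` within each individual,
  i.e. individual ``i`` (0-based position in the sorted pedigree) owns rows
  ``2*i`` (paternal gamete, received from the sire) and ``2*i + 1``
  (maternal gamete, received from the dam).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "Pedigree",
    "RelationshipMatrices",
    "additive_A",
    "gametic_L",
    "gametic_incidence_M",
    "relationship_matrices",
]


@dataclass
class Pedigree:
    """Ordered pedigree records; parent code 0 means unknown.

    Parameters
    ----------
    ids, sires, dams
        Integer identifier arrays of equal length.  Every non-zero parent id
        must appear in ``ids`` *before* its offspring.
    """

    ids: np.ndarray
    sires: np.ndarray
    dams: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sires = np.asarray(self.sires, dtype=np.int64)
        self.dams = np.asarray(self.dams, dtype=np.int64)
        if not (len(self.ids) == len(self.sires) == len(self.dams)):
            raise ValueError("id, sire and dam columns must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual ids in pedigree")
        # map ids to 0-based positions; -1 = unknown parent
        pos = {int(i): k for k, i in enumerate(self.ids)}
        self._sire_idx = np.empty(len(self.ids), dtype=np.int64)
        self._dam_idx = np.empty(len(self.ids), dtype=np.int64)
        for k, (s, d) in enumerate(zip(self.sires, self.dams)):
            for val, out in ((int(s), self._sire_idx), (int(d), self._dam_idx)):
                if val == 0:
                    out[k] = -1
                else:
                    if val not in pos:
                        raise ValueError(f"parent {val} not in pedigree")
                    out[k] = pos[val]
                    if pos[val] >= k:
                        raise ValueError(
                            f"pedigree not topologically sorted: parent {val} "
                            f"appears at or after its offspring {int(self.ids[k])}"
                        )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def sire_idx(self) -> np.ndarray:
        """0-based sire positions (-1 for unknown)."""
        return self._sire_idx

    @property
    def dam_idx(self) -> np.ndarray:
        return self._dam_idx

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a data frame with columns id, sire, dam (0 = unknown).

        Rows are re-sorted topologically if needed (by generation column when
        present, else assumed already sorted).
        """
        f = frame
        if "generation" in f.columns:
            f = f.sort_values(["generation", "id"], kind="stable")
        return cls(f["id"].to_numpy(), f["sire"].to_numpy(), f["dam"].to_numpy())


@dataclass
class RelationshipMatrices:
    """Bundle of A (n x n), L (2n x 2n), M (n x 2n) and the gamete row map."""

    ids: np.ndarray
    A: np.ndarray
    L: np.ndarray
    M: np.ndarray
    gamete_rows: dict = field(default_factory=dict)  # id -> (row_pat, row_mat)


@njit(cache=True)
def _tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * A[s, j]
            if d >= 0:
                v += 0.5 * A[d, j]
            A[i, j] = v
            A[j, i] = v
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


@njit(cache=True)
def _gametic_recursion(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = sire.shape[0]
    L = np.zeros((2 * n, 2 * n))
    for i in range(n):
        for which in range(2):  # 0 = paternal gamete (from sire), 1 = maternal (from dam)
            g = 2 * i + which
            p = sire[i] if which == 0 else dam[i]
            if p < 0:
                L[g, g] = 1.0
            else:
                pp, pm = 2 * p, 2 * p + 1
                for x in range(g):
                    v = 0.5 * (L[pp, x] + L[pm, x])
                    L[g, x] = v
                    L[x, g] = v
                L[g, g] = 1.0
    return L


def additive_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``a_ij = 0.5 * (a_sire(i),j + a_dam(i),j)`` for i after j and
    ``a_ii = 1 + 0.5 * a_sire(i),dam(i)``; unknown parents contribute 0.
    """
    return _tabular_A(pedigree.sire_idx, pedigree.dam_idx)


def gametic_L(pedigree: Pedigree) -> np.ndarray:
    """Gametic relationship matrix (2n x 2n).

    Founder gametes form an identity block.  A gamete received from parent P
    is, in expectation, the average of P's two gametes, so its relationship
    with every previously defined gamete is the mean of the parent's two
    rows; its diagonal is 1.  The covariance between the two gametes within
    an individual then equals that individual's inbreeding coefficient.
    """
    return _gametic_recursion(pedigree.sire_idx, pedigree.dam_idx)


def gametic_incidence_M(pedigree: Pedigree) -> np.ndarray:
    """Binary n x 2n map linking each individual to its own two gamete rows."""
    n = len(pedigree)
    M = np.zeros((n, 2 * n))
    idx = np.arange(n)
    M[idx, 2 * idx] = 1.0
    M[idx, 2 * idx + 1] = 1.0
    return M


def relationship_matrices(pedigree: Pedigree) -> RelationshipMatrices:
    """Compute A, L and M together with the id -> gamete-row map."""
    A = additive_A(pedigree)
    L = gametic_L(pedigree)
    M = gametic_incidence_M(pedigree)
    rows = {int(i): (2 * k, 2 * k + 1) for k, i in enumerate(pedigree.ids)}
    return RelationshipMatrices(ids=pedigree.ids.copy(), A=A, L=L, M=M, gamete_rows=rows)
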