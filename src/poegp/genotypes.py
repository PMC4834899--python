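"""Origin-resolved genotype container.

Phased, parent-assigned biallelic genotypes are stored as a pair of binary
indicator matrices: ``maternal[i, j]`` is 1 when individual ``i`` received an
A1 allele at marker ``j`` from its dam, and ``paternal`` likewise for the
sire.  The ordinary additive genotype code is their sum,
``W = maternal + paternal`` in {0, 1, 2}, which collapses the two reciprocal
heterozygotes A1A2 and A2A1 onto the same value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OrderedGenotypes"]


@dataclass
class OrderedGenotypes:
    ids: np.ndarray
    marker_ids: np.ndarray
    maternal: np.ndarray  # n x p, entries in {0, 1}: count of A1 from the dam
    paternal: np.ndarray  # n x p, entries in {0, 1}: count of A1 from the sire

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.marker_ids = np.asarray(self.marker_ids)
        self.maternal = np.ascontiguousarray(self.maternal, dtype=np.int8)
        self.paternal = np.ascontiguousarray(self.paternal, dtype=np.int8)
        n, p = self.maternal.shape
        if self.paternal.shape != (n, p):
            raise ValueError("maternal and paternal matrices are not conformable")
        if len(self.ids) != n or len(self.marker_ids) != p:
            raise ValueError("id / marker id lengths do not match matrices")
        for m in (self.maternal, self.paternal):
            bad = (m != 0) & (m != 1)
            if bad.any():
                raise ValueError("allele indicator matrices must be binary")

    @property
    def n_individuals(self) -> int:
        return self.maternal.shape[0]

    @property
    def n_markers(self) -> int:
        return self.maternal.shape[1]

    @property
    def W(self) -> np.ndarray:
        """Additive genotype codes: 0 (A2A2), 1 (either heterozygote), 2 (A1A1)."""
        return (self.maternal + self.paternal).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        """Sample frequency of the A1 allele per marker."""
        return self.W.mean(axis=0) / 2.0

    def subset_markers(self, index: np.ndarray) -> "OrderedGenotypes":
        return OrderedGenotypes(
            ids=self.ids,
            marker_ids=self.marker_ids[index],
            maternal=self.maternal[:, index],
            paternal=self.paternal[:, index],
        )

    def subset_individuals(self, index: np.ndarray) -> "OrderedGenotypes":
        return OrderedGenotypes(
            ids=self.ids[index],
            marker_ids=self.marker_ids,
            maternal=self.maternal[index],
            paternal=self.paternal[index],
        )
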