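"""Kinship from expected founder-allele sharing.

For samples i and e the kinship entry is the average over markers of the
cosine similarity of their founder-dosage vectors:

    k_ie = (1/M) * sum_j  sum_h d_ij(h) d_ej(h)
                          / sqrt(sum_h d_ij(h)^2) / sqrt(sum_h d_ej(h)^2)

Self-similarity is 1 at every marker, so the diagonal is exactly 1; entries
lie in [0, 1].  The matrix is not forced positive semidefinite — the mixed
model solver adds a small diagonal jitter if a factorization fails.  A
leave-one-chromosome-out (LOCO) variant omits the scanned chromosome's
markers so the polygenic term does not absorb the locus under test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome import MarkerMap


@dataclass
class KinshipMatrix:
    """Symmetric n x n expected allele-sharing matrix."""

    values: np.ndarray
    n_markers: int
    excluded_chrom: object = None

    def __post_init__(self):
        K = np.asarray(self.values, float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.values = K

    @property
    def n(self) -> int:
        return self.values.shape[0]


def kinship_from_dosage(dosage: np.ndarray, map: MarkerMap | None = None,
                        exclude_chrom=None) -> KinshipMatrix:
    """Expected allele-sharing kinship from founder dosages (n, M, F).

    With ``exclude_chrom`` set, markers on that chromosome are omitted
    (LOCO).  Markers where any sample has a zero dosage vector are skipped
    with a warning.
    """
    d = np.asarray(dosage, float)
    n, M, F = d.shape
    keep = np.ones(M, dtype=bool)
    if exclude_chrom is not None:
        if map is None:
            raise ValueError("a marker map is required to exclude a chromosome")
        keep &= (map.table["chr"].to_numpy() != exclude_chrom)
        if not keep.any():
            raise ValueError("no markers remain after chromosome exclusion")
    norms = np.sqrt((d**2).sum(axis=2))  # (n, M)
    zero = (norms == 0).any(axis=0)
    if zero.any():
        warnings.warn(f"skipping {int(zero.sum())} markers with zero dosage vectors")
        keep &= ~zero
    dk = d[:, keep] / norms[:, keep, None]
    Mk = dk.shape[1]
    K = np.einsum("imh,emh->ie", dk, dk) / Mk
    # exact symmetry and unit diagonal despite float accumulation order
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return KinshipMatrix(K, Mk, exclude_chrom)


def loco_kinship(dosage: np.ndarray, map: MarkerMap) -> dict:
    """Chromosome -> kinship computed from all other chromosomes."""
    return {c: kinship_from_dosage(dosage, map, exclude_chrom=c)
            for c in map.chromosomes}
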