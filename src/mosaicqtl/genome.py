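"""Core domain types: founder panels, marker maps, and the diplotype state algebra.

A multiparent outbred animal carries, at every locus, an unordered pair of
founder haplotypes (its *diplotype*).  With F founders there are F(F+1)/2
diplotype states: F homozygous plus F(F-1)/2 heterozygous.  For the standard
eight-founder panel (founders coded A-H) that is 36 states, and every
downstream array in this package indexes its state axis by the fixed ordering
defined here: the F homozygotes first, in founder order, then the
heterozygotes in lexicographic order (AB, AC, ..., GH).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Default eight-founder panel codes.
DEFAULT_FOUNDER_CODES = ("A", "B", "C", "D", "E", "F", "G", "H")

DEFAULT_FOUNDER_NAMES = {
    "A": "A/J",
    "B": "C57BL/6J",
    "C": "129S1/SvImJ",
    "D": "NOD/ShiLtJ",
    "E": "NZO/HlLtJ",
    "F": "CAST/EiJ",
    "G": "PWK/PhJ",
    "H": "WSB/EiJ",
}


@dataclass(frozen=True)
class FounderPanel:
    """Ordered panel of inbred founder strains.

    Parameters
    ----------
    labels
        Unique one-letter (or short) founder codes, in panel order.
    names
        Optional display names, parallel to ``labels``.
    """

    labels: tuple[str, ...] = DEFAULT_FOUNDER_CODES
    names: tuple[str, ...] = ()

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a founder panel needs at least 2 founders")
        if len(set(labels)) != len(labels):
            raise ValueError("founder labels must be unique")
        if not self.names:
            names = tuple(DEFAULT_FOUNDER_NAMES.get(l, l) for l in labels)
            object.__setattr__(self, "names", names)

    @property
    def n_founders(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown founder {label!r}") from None


class DiplotypeStateSpace:
    """The ordered set of unordered founder pairs for a panel.

    States are ordered deterministically: homozygotes first in founder order,
    then heterozygotes lexicographically.  ``N`` holds the founder-count
    matrix N_h(s) (founders x states), i.e. how many alleles of founder h a
    diplotype s carries; each column sums to 2.
    """

    def __init__(self, panel: FounderPanel):
        self.panel = panel
        F = panel.n_founders
        pairs: list[tuple[int, int]] = [(h, h) for h in range(F)]
        pairs += [(h, k) for h in range(F) for k in range(h + 1, F)]
        self.pairs = tuple(pairs)
        self.states = tuple(
            panel.labels[h] + panel.labels[k] for h, k in pairs
        )
        self._index = {s: i for i, s in enumerate(self.states)}
        N = np.zeros((F, len(pairs)), dtype=np.int8)
        for s, (h, k) in enumerate(pairs):
            N[h, s] += 1
            N[k, s] += 1
        self.N = N
        self.is_homozygous = np.array([h == k for h, k in pairs])

    @property
    def n_states(self) -> int:
        return len(self.pairs)

    def index(self, state: str) -> int:
        key = state
        if key not in self._index and len(state) == 2:
            key = state[1] + state[0]
        if key not in self._index:
            raise KeyError(f"unknown diplotype state {state!r}")
        return self._index[key]

    def founder_count(self, founder: str, state: str | int) -> int:
        """N_h(s): number of alleles of ``founder`` in diplotype ``state``."""
        h = self.panel.index(founder)
        s = state if isinstance(state, (int, np.integer)) else self.index(state)
        return int(self.N[h, s])

    def __len__(self) -> int:
        return self.n_states

    def __repr__(self) -> str:
        return f"DiplotypeStateSpace(F={self.panel.n_founders}, states={self.n_states})"


def enumerate_diplotypes(panel: FounderPanel) -> DiplotypeStateSpace:
    """Enumerate all unordered founder pairs of a panel.

    For F founders this yields F(F+1)/2 states (36 for the eight-founder
    panel: 8 homozygous, 28 heterozygous), in the package's canonical order.
    """
    return DiplotypeStateSpace(panel)


@dataclass
class MarkerMap:
    """Genotyping-array marker map with physical (bp) and genetic (cM) positions.

    Within each chromosome, marker positions must be strictly increasing in
    both coordinates; bp positions are 1-based.
    """

    table: pd.DataFrame  # columns: marker, chr, bp, cM

    REQUIRED = ("marker", "chr", "bp", "cM")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"marker map missing columns: {missing}")
        if t["marker"].duplicated().any():
            dup = t.loc[t["marker"].duplicated(), "marker"].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        if (t["bp"] < 1).any():
            raise ValueError("bp positions must be >= 1 (1-based)")
        if (t["cM"] < 0).any():
            raise ValueError("cM positions must be non-negative")
        for chrom, sub in t.groupby("chr", sort=False):
            for col in ("bp", "cM"):
                v = sub[col].to_numpy()
                if not np.all(np.diff(v) > 0):
                    raise ValueError(
                        f"marker positions not strictly increasing in {col} "
                        f"on chromosome {chrom}"
                    )
        self.table = t.reset_index(drop=True)

    @property
    def markers(self) -> np.ndarray:
        return self.table["marker"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chr"]))

    @property
    def autosomes(self) -> list:
        return [c for c in self.chromosomes if str(c).upper() != "X"]

    def chrom_slice(self, chrom) -> slice:
        idx = np.flatnonzero(self.table["chr"].to_numpy() == chrom)
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, chrom) -> "MarkerMap":
        sl = self.chrom_slice(chrom)
        return MarkerMap(self.table.iloc[sl].reset_index(drop=True))

    def cM(self, chrom=None) -> np.ndarray:
        if chrom is None:
            return self.table["cM"].to_numpy(float)
        return self.table.iloc[self.chrom_slice(chrom)]["cM"].to_numpy(float)

    def bp(self, chrom=None) -> np.ndarray:
        if chrom is None:
            return self.table["bp"].to_numpy(np.int64)
        return self.table.iloc[self.chrom_slice(chrom)]["bp"].to_numpy(np.int64)

    def cm_to_bp(self, chrom, cm: np.ndarray) -> np.ndarray:
        """Interpolate bp from cM along one chromosome (linear between markers)."""
        sub = self.table.iloc[self.chrom_slice(chrom)]
        return np.interp(cm, sub["cM"].to_numpy(float), sub["bp"].to_numpy(float))


CALL_CODES = ("A", "H", "B", "N")
CALL_INDEX = {c: i for i, c in enumerate(CALL_CODES)}


@dataclass
class GenotypeCalls:
    """Sample x marker genotype-call matrix over {A, H, B, N}.

    ``A`` = homozygous reference, ``B`` = homozygous alternative, ``H`` =
    heterozygous, ``N`` = no call.  Stored as small integers (see
    ``CALL_CODES``); ``N`` is an informative outcome, not missing data.
    """

    samples: list[str]
    calls: np.ndarray  # (n_samples, n_markers) int8 codes into CALL_CODES

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.samples):
            raise ValueError("call matrix shape does not match sample list")
        if self.calls.min(initial=0) < 0 or self.calls.max(initial=0) > 3:
            raise ValueError("call codes out of range")

    @classmethod
    def from_symbols(cls, samples: Sequence[str], symbols: np.ndarray) -> "GenotypeCalls":
        symbols = np.asarray(symbols, dtype="U1")
        codes = np.full(symbols.shape, -1, dtype=np.int8)
        for sym, code in CALL_INDEX.items():
            codes[symbols == sym] = code
        if (codes < 0).any():
            i, j = np.argwhere(codes < 0)[0]
            raise ValueError(
                f"unknown call symbol {symbols[i, j]!r} at sample row {i}, marker column {j}"
            )
        return cls(list(samples), codes)

    def to_symbols(self) -> np.ndarray:
        return np.array(CALL_CODES, dtype="U1")[self.calls]

    @property
    def shape(self) -> tuple[int, int]:
        return self.calls.shape


@dataclass
class IntensityData:
    """Two-channel (X, Y) array intensities, one pair of sample x marker matrices."""

    samples: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("X and Y intensity matrices must have the same shape")
        if self.x.shape[0] != len(self.samples):
            raise ValueError("intensity matrix shape does not match sample list")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.x.shape


@dataclass
class DiplotypeProbs:
    """Posterior diplotype probabilities p_ij(s), sample x marker x state."""

    samples: list[str]
    probs: np.ndarray  # (n_samples, n_markers, n_states)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise ValueError("diplotype probabilities must be 3-d")
        if self.probs.min() < -1e-12 or self.probs.max() > 1 + 1e-12:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("diplotype probabilities must sum to 1 per (sample, marker)")

    @property
    def shape(self):
        return self.probs.shape


@dataclass
class PhasedReconstruction:
    """Phased founder-label haplotypes per sample per chromosome.

    ``hap1``/``hap2`` map chromosome -> (n_samples, n_markers_chrom) integer
    founder indices; ``breakpoints_bp`` maps (sample, chromosome) -> list of
    bp midpoints between the flanking markers of each ancestry switch.
    """

    samples: list[str]
    hap1: dict
    hap2: dict
    breakpoints_bp: dict = field(default_factory=dict)

    def unordered_pairs(self, chrom) -> np.ndarray:
        """(n_samples, n_markers, 2) sorted founder-index pairs at each marker."""
        h1, h2 = self.hap1[chrom], self.hap2[chrom]
        stacked = np.stack([h1, h2], axis=-1)
        return np.sort(stacked, axis=-1)


def expected_genotype(founder_alleles: np.ndarray, space: DiplotypeStateSpace) -> np.ndarray:
    """Expected diallelic genotype call for each diplotype state at each marker.

    Parameters
    ----------
    founder_alleles
        (n_markers, F) matrix of 0/1 allele codes per founder (0 = reference
        allele -> call ``A`` when homozygous; 1 = alternative -> ``B``).
    space
        Diplotype state space for the panel.

    Returns
    -------
    (n_markers, n_states) int8 codes into ``CALL_CODES`` (A, H or B only).
    """
    founder_alleles = np.atleast_2d(np.asarray(founder_alleles))
    F = space.panel.n_founders
    if founder_alleles.shape[1] != F:
        raise ValueError("founder allele table width does not match panel size")
    if np.isnan(founder_alleles.astype(float)).any():
        raise ValueError("missing founder allele in table")
    h_idx = np.array([p[0] for p in space.pairs])
    k_idx = np.array([p[1] for p in space.pairs])
    a1 = founder_alleles[:, h_idx]
    a2 = founder_alleles[:, k_idx]
    # allele sum 0 -> A, 1 -> H, 2 -> B; CALL_CODES order is (A, H, B, N)
    geno = (a1 + a2).astype(np.int8)
    return geno
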