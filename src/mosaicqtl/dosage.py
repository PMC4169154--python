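"""Founder allelic dosages and genome-wide SNP imputation.

The diplotype posteriors p_ij(s) convert to founder allelic dosages

    d_ij(h) = sum_s p_ij(s) * N_h(s),

the expected number of alleles animal i carries from founder h at marker j
(the eight dosages always sum to 2).  Given a founder SNP table, the
expected biallelic genotype at any SNP is

    g_ij = sum_h d_ij(h) * G_j(h),

where G_j(h) indicates whether founder h carries the reference allele.
Dosages at off-array SNPs use the unweighted average of the two flanking
markers' diplotype posteriors; SNPs within an inter-marker interval that
share a strain distribution pattern (SDP) get identical imputed dosages, so
scans compute one test per distinct SDP per interval and broadcast it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import DiplotypeProbs, DiplotypeStateSpace, MarkerMap, PhasedReconstruction


def dosage_from_probs(probs: np.ndarray | DiplotypeProbs,
                      space: DiplotypeStateSpace) -> np.ndarray:
    """Founder allelic dosages d_ij(h) from diplotype posteriors.

    Accepts a (..., S) probability array or a ``DiplotypeProbs``; returns an
    array with the state axis replaced by an F-founder axis, entries in
    [0, 2] and summing to 2.
    """
    p = probs.probs if isinstance(probs, DiplotypeProbs) else np.asarray(probs, float)
    return p @ space.N.T.astype(float)


@dataclass
class SdpTable:
    """Strain distribution patterns of SNPs: which founders carry the reference.

    ``patterns`` holds one integer bitmask per SNP (bit h set = founder h
    carries the reference allele); monomorphic patterns (all founders alike)
    are flagged and excluded from scans.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    patterns: np.ndarray  # uint, bit h = founder h carries reference allele
    n_founders: int = 8

    def __post_init__(self):
        self.patterns = np.asarray(self.patterns, np.uint32)
        if (self.patterns >= (1 << self.n_founders)).any():
            raise ValueError("SDP bitmask exceeds founder count")

    @classmethod
    def from_alleles(cls, snp_id, chrom, bp, alleles: np.ndarray) -> "SdpTable":
        """Build from a (n_snps, F) 0/1 allele matrix (0 = reference)."""
        alleles = np.asarray(alleles)
        F = alleles.shape[1]
        bits = ((alleles == 0).astype(np.uint32) << np.arange(F, dtype=np.uint32)).sum(axis=1)
        return cls(np.asarray(snp_id), np.asarray(chrom), np.asarray(bp, np.int64),
                   bits, n_founders=F)

    def indicator(self) -> np.ndarray:
        """(n_snps, F) 0/1 matrix G_j(h): founder carries the reference allele."""
        return ((self.patterns[:, None] >> np.arange(self.n_founders)) & 1).astype(float)

    @property
    def monomorphic(self) -> np.ndarray:
        full = (1 << self.n_founders) - 1
        return (self.patterns == 0) | (self.patterns == full)

    def __len__(self):
        return len(self.patterns)


def interval_average(probs: np.ndarray, map: MarkerMap, chrom, snp_bp) -> np.ndarray:
    """Diplotype posterior at an arbitrary bp position on one chromosome.

    Unweighted mean of the two flanking markers' posteriors; positions before
    the first or past the last marker take the nearest marker's posterior.
    ``probs`` is (n, M, S) over the full map.
    """
    sl = map.chrom_slice(chrom)
    bp = map.bp(chrom)
    sub = probs[:, sl]
    snp_bp = np.atleast_1d(np.asarray(snp_bp, np.int64))
    right = np.searchsorted(bp, snp_bp, side="left")
    left = right - 1
    at_marker = (right < len(bp)) & (bp[np.minimum(right, len(bp) - 1)] == snp_bp)
    left = np.clip(left, 0, len(bp) - 1)
    right = np.clip(right, 0, len(bp) - 1)
    out = 0.5 * (sub[:, left] + sub[:, right])
    out[:, at_marker] = sub[:, right[at_marker]]
    return out if out.shape[1] > 1 else out[:, 0]


def impute_snp_dosage(founder_dosage: np.ndarray, sdp: SdpTable,
                      snp_index=None) -> np.ndarray:
    """Imputed reference-allele dosage g_ij from founder dosages at SNP loci.

    ``founder_dosage`` is (n, n_snps, F) (founder dosages interpolated at the
    SNP positions); returns (n, n_snps) in [0, 2].
    """
    G = sdp.indicator()
    if snp_index is not None:
        G = G[np.atleast_1d(snp_index)]
    g = np.einsum("nsf,sf->ns", founder_dosage, G)
    return np.clip(g, 0.0, 2.0)


def assign_intervals(map: MarkerMap, sdp: SdpTable) -> np.ndarray:
    """Inter-marker interval index per SNP, genome-wide.

    SNPs fall into half-open intervals [left marker, right marker) by bp;
    positions before the first marker join interval 0, past the last marker
    the final interval.  Interval ids are unique across chromosomes.
    """
    interval = np.full(len(sdp), -1, dtype=np.int64)
    offset = 0
    for chrom in map.chromosomes:
        bp = map.bp(chrom)
        mask = sdp.chrom == chrom
        if mask.any():
            idx = np.searchsorted(bp, sdp.bp[mask], side="right") - 1
            idx = np.clip(idx, 0, len(bp) - 2 if len(bp) > 1 else 0)
            interval[mask] = idx + offset
        offset += max(len(bp) - 1, 1)
    if (interval < 0).any():
        bad = np.asarray(sdp.chrom)[interval < 0][0]
        raise KeyError(f"SNP on unknown chromosome {bad!r}")
    return interval


def collapse_sdp(map: MarkerMap, sdp: SdpTable):
    """Group SNPs by (interval, SDP): one regression per group.

    Returns ``(group_id, representatives)`` — per-SNP group index and, per
    group, the index of one representative SNP.
    """
    interval = assign_intervals(map, sdp)
    key = interval.astype(np.uint64) << np.uint64(32) | sdp.patterns.astype(np.uint64)
    _, rep, inverse = np.unique(key, return_index=True, return_inverse=True)
    return inverse, rep


def impute_marginal_genome(recon: PhasedReconstruction, map: MarkerMap,
                           sdp: SdpTable) -> np.ndarray:
    """Hard diploid SNP genotypes from a phased marginal reconstruction.

    Each SNP inherits the two founder alleles of the haplotype strands at
    the nearest flanking marker (left marker of the containing interval;
    SNPs before the first marker use it).  Returns (n, n_snps) integer
    reference-allele counts in {0, 1, 2}.
    """
    G = sdp.indicator()  # (n_snps, F) reference indicator
    n = len(recon.samples)
    out = np.empty((n, len(sdp)), dtype=np.int8)
    for chrom in map.chromosomes:
        mask = np.flatnonzero(sdp.chrom == chrom)
        if mask.size == 0:
            continue
        bp = map.bp(chrom)
        j = np.clip(np.searchsorted(bp, sdp.bp[mask], side="right") - 1, 0, len(bp) - 1)
        h1 = recon.hap1[chrom][:, j].astype(np.int64)  # (n, n_snps_c)
        h2 = recon.hap2[chrom][:, j].astype(np.int64)
        Gm = G[mask]  # (n_snps_c, F)
        cols = np.arange(mask.size)[None, :]
        out[:, mask] = (Gm[cols, h1] + Gm[cols, h2]).astype(np.int8)
    return out


def random_sdp_table(map: MarkerMap, snps_per_interval: int = 3,
                     maf_range=(1, 7), rng=None, n_founders: int = 8) -> SdpTable:
    """Synthetic founder SNP table: random SDPs placed inside each interval."""
    rng = np.random.default_rng(rng)
    ids, chroms, bps, pats = [], [], [], []
    for chrom in map.chromosomes:
        bp = map.bp(chrom)
        for k in range(len(bp) - 1):
            lo, hi = bp[k], bp[k + 1]
            pos = np.sort(rng.integers(lo, hi, size=snps_per_interval))
            for q, p in enumerate(pos):
                n_alt = rng.integers(maf_range[0], maf_range[1] + 1)
                alt = rng.choice(n_founders, size=n_alt, replace=False)
                pattern = ((1 << n_founders) - 1) & ~int(np.bitwise_or.reduce(
                    (1 << alt.astype(np.uint32))))
                ids.append(f"snp_{chrom}_{k}_{q}")
                chroms.append(chrom)
                bps.append(int(p))
                pats.append(pattern)
    return SdpTable(np.array(ids), np.array(chroms, dtype=object),
                    np.array(bps, np.int64), np.array(pats, np.uint32),
                    n_founders=n_founders)


def sdp_table_to_frame(sdp: SdpTable, founder_labels) -> pd.DataFrame:
    """CSV-friendly view: one 0/1 reference-allele column per founder."""
    G = sdp.indicator().astype(int)
    df = pd.DataFrame({"snp": sdp.snp_id, "chr": sdp.chrom, "bp": sdp.bp})
    for h, lab in enumerate(founder_labels):
        df[lab] = G[:, h]
    return df
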