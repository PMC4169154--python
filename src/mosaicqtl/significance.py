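"""Genome-wide significance thresholds and QTL support intervals.

Two threshold procedures:

* **Bonferroni** — -log10(alpha / n_tests), conservative but instantaneous;
* **permutation** — phenotype rows (with their covariates, as a unit) are
  permuted against the genotypes; each permuted data set is scanned with a
  plain linear model *without* the kinship term, and the threshold is the
  empirical (1 - alpha) quantile of the per-permutation maximum statistic
  over the autosomes.  Omitting the kinship term in the permutation scans
  yields slightly conservative thresholds for the mixed-model scan while
  keeping the permutations cheap; the package's type-I simulations verify
  the resulting genome-wide error control.

Support intervals use the 95% Bayesian credible interval: the LOD curve is
transformed to 10^LOD, its area is approximated by trapezoids between the
marker positions, and the interval is grown outward from the peak until it
covers the requested fraction of the area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dosage import SdpTable, dosage_from_probs
from .genome import DiplotypeStateSpace, MarkerMap
from .scan import MODEL_DF, _batched_lod, scan


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Genome-wide -log10(p) threshold under Bonferroni correction."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(-np.log10(alpha / n_tests))


@dataclass
class PermutationResult:
    """Null distribution of the genome-wide maximum statistic."""

    maxima: np.ndarray
    alpha: float
    seed: int | None
    statistic: str = "lod"

    @property
    def n_perm(self) -> int:
        return len(self.maxima)

    def threshold(self, alpha: float | None = None) -> float:
        """Empirical (1 - alpha) quantile of the stored maxima."""
        a = self.alpha if alpha is None else alpha
        return float(np.quantile(self.maxima, 1.0 - a, method="higher"))


def permutation_threshold(probs, space: DiplotypeStateSpace, map: MarkerMap,
                          y: np.ndarray, model: str = "additive_haplotype",
                          covariates: np.ndarray | None = None,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed=None, sdp: SdpTable | None = None,
                          autosomes_only: bool = True) -> PermutationResult:
    """Permutation null distribution of the genome-wide max LOD.

    The scans are plain linear models (no kinship term).  Phenotype and
    covariate rows are permuted together, preserving their association while
    breaking genotype-phenotype links.  Batched across permutations.
    """
    if n_perm < 10:
        raise ValueError("fewer than 10 permutations is not meaningful")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    n = len(y)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)], axis=1)  # (n, P)
    Y = y[perms]                      # (n, P) permuted phenotypes
    if covariates is not None and covariates.size:
        # covariates move with the phenotype: equivalently, residualize both
        # against the permuted covariates; done per permutation below.
        C = np.asarray(covariates, float)
        maxima = np.empty(n_perm)
        for pidx in range(n_perm):
            res = scan(model, probs, space, map, Y[:, pidx], kinship=None,
                       covariates=C[perms[:, pidx]], sdp=sdp)
            maxima[pidx] = _max_stat(res, map, autosomes_only)
        return PermutationResult(maxima, alpha, seed)
    maxima = _batched_null_max(probs, space, map, Y, model, sdp, autosomes_only)
    return PermutationResult(maxima, alpha, seed)


def null_max_lods(probs, space, map: MarkerMap, n_null: int,
                  model: str = "additive_haplotype", seed=None,
                  sdp: SdpTable | None = None,
                  autosomes_only: bool = True) -> PermutationResult:
    """Max-LOD null distribution from iid N(0,1) phenotypes (no permutation).

    This is the threshold calibration used by the power and type-I studies:
    scan ``n_null`` independent standard-normal phenotypes with the plain
    linear model and keep each scan's autosomal maximum.
    """
    rng = np.random.default_rng(seed)
    n = probs.shape[0]
    Y = rng.standard_normal((n, n_null))
    maxima = _batched_null_max(probs, space, map, Y, model, sdp, autosomes_only)
    return PermutationResult(maxima, 0.05, seed)


def _max_stat(res, map: MarkerMap, autosomes_only: bool) -> float:
    t = res.table
    if autosomes_only:
        t = t[t["chr"].isin(map.autosomes)]
    return float(t["lod"].max())


def _batched_null_max(probs, space, map: MarkerMap, Y: np.ndarray, model: str,
                      sdp, autosomes_only: bool) -> np.ndarray:
    """Per-column maximum LOD over loci for a matrix of phenotypes.

    Plain linear model with intercept only; projection bases are built once
    per locus (SVD, rank-safe) and reused for every phenotype column.
    """
    p = probs.probs if hasattr(probs, "probs") else np.asarray(probs, float)
    n, P = Y.shape
    if model == "full":
        G_all = p
    elif model == "additive_haplotype":
        G_all = dosage_from_probs(p, space)
    elif model == "additive_snp":
        if sdp is None:
            raise ValueError("additive SNP nulls require a founder SNP table")
        G_all = _snp_predictors(p, space, map, sdp)
    else:
        raise ValueError(f"unknown model {model!r}")

    Yc = Y - Y.mean(axis=0, keepdims=True)
    tss = (Yc**2).sum(axis=0)         # RSS0 per phenotype (intercept-only null)
    chroms = map.autosomes if autosomes_only else map.chromosomes
    best = np.zeros(P)
    ones = np.ones((n, 1)) / np.sqrt(n)
    for chrom in chroms:
        if model == "additive_snp":
            Gc = G_all[chrom]
        else:
            Gc = G_all[:, map.chrom_slice(chrom)]
        for k in range(Gc.shape[1]):
            X = np.column_stack([ones, Gc[:, k]])
            Q = _orth_basis(X)
            proj = Q.T @ Yc
            rss1 = np.maximum(tss - (proj**2).sum(axis=0), 1e-300)
            lod = 0.5 * n * np.log10(np.maximum(tss / rss1, 1.0))
            np.maximum(best, lod, out=best)
    return best


def _snp_predictors(p, space, map: MarkerMap, sdp: SdpTable) -> dict:
    from .dosage import collapse_sdp, interval_average
    group_id, rep = collapse_sdp(map, sdp)
    dos = dosage_from_probs(p, space)
    Gind = sdp.indicator()
    mono = sdp.monomorphic
    out = {}
    rep_chrom = sdp.chrom[rep]
    for chrom in map.chromosomes:
        take = np.flatnonzero(rep_chrom == chrom)
        if take.size == 0:
            out[chrom] = np.zeros((dos.shape[0], 0, 1))
            continue
        snp_idx = rep[take]
        davg = interval_average(dos, map, chrom, sdp.bp[snp_idx])
        if davg.ndim == 2:
            davg = davg[:, None, :]
        g = np.einsum("nlf,lf->nl", davg, Gind[snp_idx])[:, :, None]
        g[:, mono[snp_idx], :] = 0.0
        out[chrom] = g
    return out


def _orth_basis(X: np.ndarray) -> np.ndarray:
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    r = (s > s[0] * 1e-10).sum() if s.size else 0
    return u[:, :r]


@dataclass
class SupportInterval:
    """Bayesian credible interval for QTL location on one chromosome."""

    chrom: object
    lower_bp: int
    upper_bp: int
    level: float
    peak_bp: int
    whole_chromosome: bool = False

    @property
    def width_bp(self) -> int:
        return self.upper_bp - self.lower_bp


def credible_interval(lod: np.ndarray, bp: np.ndarray, chrom=None,
                      level: float = 0.95, hpd: bool = False) -> SupportInterval:
    """Support interval covering ``level`` of the area under 10^LOD.

    The transformed curve's area is integrated with trapezoids between the
    marker positions.  By default the interval grows outward from the peak
    marker, at each step absorbing whichever flanking trapezoid carries more
    area, until coverage is reached; endpoints land on marker positions.
    With ``hpd=True`` segments are instead accumulated in decreasing order
    of area and the interval is the span of the selected segments (a
    contiguous-by-construction highest-density variant for unimodal curves).
    """
    lod = np.asarray(lod, float)
    bp = np.asarray(bp, np.int64)
    if len(lod) < 2:
        raise ValueError("need at least 2 markers for a support interval")
    peak = int(np.argmax(lod))
    z = 10.0 ** (lod - lod.max())       # rescaled for overflow safety
    seg = 0.5 * (z[:-1] + z[1:]) * np.diff(bp)   # trapezoid areas
    total = seg.sum()
    if total <= 0 or np.allclose(lod, lod[0]):
        return SupportInterval(chrom, int(bp[0]), int(bp[-1]), level,
                               int(bp[peak]), whole_chromosome=True)
    if hpd:
        order = np.argsort(seg)[::-1]
        acc, chosen = 0.0, []
        for k in order:
            chosen.append(k)
            acc += seg[k]
            if acc >= level * total:
                break
        lo = min(chosen)
        hi = max(chosen) + 1
        return SupportInterval(chrom, int(bp[lo]), int(bp[hi]), level, int(bp[peak]))
    lo = hi = peak
    acc = 0.0
    while acc < level * total and (lo > 0 or hi < len(lod) - 1):
        left = seg[lo - 1] if lo > 0 else -np.inf
        right = seg[hi] if hi < len(lod) - 1 else -np.inf
        if left >= right:
            lo -= 1
            acc += seg[lo]
        else:
            acc += seg[hi]
            hi += 1
    return SupportInterval(chrom, int(bp[lo]), int(bp[hi]), level, int(bp[peak]))
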