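"""Kinship-corrected genome scans.

Three locus models are supported, all sharing the same mixed-model backbone
y = covariates + locus term + polygenic + error, cov(polygenic) = sigma_g^2 K:

* **full** — unconstrained regression on the 36 diplotype-state posterior
  probabilities (35 df): arbitrary additive and dominance patterns;
* **additive haplotype** — regression on the 8 founder allelic dosages
  (7 df): founder alleles act additively;
* **additive SNP** — regression on the imputed biallelic SNP dosage (1 df),
  computed once per distinct strain-distribution pattern per inter-marker
  interval and broadcast to all SNPs in the group.

Variance components are estimated once per phenotype under the null model
(no locus term) by maximum likelihood on the eigendecomposition of K, then
held fixed across loci; each locus is then a generalized least squares fit
and LOD = (n/2) log10(RSS0/RSS1) on the whitened data.  P-values come from
the chi-square asymptotics of the likelihood-ratio statistic at the model's
degrees of freedom.  With K proportional to the identity the whole procedure
reduces exactly to ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .dosage import SdpTable, collapse_sdp, dosage_from_probs, interval_average
from .genome import DiplotypeProbs, DiplotypeStateSpace, MarkerMap
from .kinship import KinshipMatrix

LN10 = np.log(10.0)

MODEL_DF = {"full": 35, "additive_haplotype": 7, "additive_snp": 1}


@dataclass
class PhenotypeTable:
    """Phenotype and covariates aligned to the genotyped samples."""

    table: pd.DataFrame  # columns: sample, phenotype, covariates...
    phenotype: str = "phenotype"

    def aligned(self, samples) -> "PhenotypeTable":
        t = self.table.set_index("sample").loc[list(samples)].reset_index()
        missing = t[self.phenotype].isna()
        if missing.any():
            warnings.warn(f"dropping {int(missing.sum())} samples with missing phenotype")
            t = t[~missing]
        return PhenotypeTable(t, self.phenotype)

    @property
    def y(self) -> np.ndarray:
        return self.table[self.phenotype].to_numpy(float)

    def design_matrix(self, covariates=()) -> np.ndarray:
        """Intercept plus covariate columns; categoricals one-hot, first level
        as reference; aliased columns dropped with a warning."""
        n = len(self.table)
        cols = [np.ones(n)]
        for c in covariates:
            col = self.table[c]
            if col.dtype.kind in "if":
                cols.append(col.to_numpy(float))
            else:
                dummies = pd.get_dummies(col, drop_first=True)
                for d in dummies.columns:
                    cols.append(dummies[d].to_numpy(float))
        X = np.column_stack(cols)
        r = np.linalg.matrix_rank(X)
        if r < X.shape[1]:
            warnings.warn("covariate matrix is singular; dropping aliased columns")
            _, R, piv = _qr_pivot(X)
            keep = np.sort(piv[:r])
            X = X[:, keep]
        return X


def _qr_pivot(X):
    from scipy.linalg import qr
    return qr(X, mode="economic", pivoting=True)


@dataclass
class MixedModelFit:
    """Null-model variance components and fixed effects."""

    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    loglik: float
    h2: float
    eigvals: np.ndarray = field(repr=False, default=None)
    eigvecs: np.ndarray = field(repr=False, default=None)

    @property
    def weights(self) -> np.ndarray:
        """Per-eigencomponent variance scale h*lambda + (1-h)."""
        h = self.h2
        return h * self.eigvals + (1.0 - h)


def fit_null(y: np.ndarray, covariates: np.ndarray,
             kinship: KinshipMatrix | np.ndarray,
             eig: tuple | None = None) -> MixedModelFit:
    """ML fit of y = X a + polygenic + error with cov(polygenic) = sg^2 K.

    One-dimensional profile likelihood over the heritability ratio
    h = sg^2 / (sg^2 + se^2) on the eigendecomposition of K; the total
    variance is profiled out analytically.  ``eig=(eigenvalues,
    eigenvectors)`` skips the decomposition when the caller already has it.
    """
    y = np.asarray(y, float)
    n = len(y)
    X = np.asarray(covariates, float)
    if n < X.shape[1] + 2:
        raise ValueError("too few samples for the fixed-effect design")
    if eig is not None:
        lam, U = eig
    else:
        K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship)
        try:
            lam, U = np.linalg.eigh(K)
        except np.linalg.LinAlgError:
            lam, U = np.linalg.eigh(K + 1e-6 * np.eye(n))
    lam = np.maximum(lam, 0.0)
    yr = U.T @ y
    Xr = U.T @ X

    def negll(h):
        w = h * lam + (1.0 - h)
        sw = 1.0 / np.sqrt(w)
        Xw = Xr * sw[:, None]
        yw = yr * sw
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        r = yw - Xw @ beta
        s2 = (r @ r) / n
        s2 = max(s2, 1e-300)
        return 0.5 * (n * np.log(2 * np.pi * s2) + np.log(w).sum() + n)

    res = minimize_scalar(negll, bounds=(0.0, 1.0 - 1e-6), method="bounded",
                          options={"xatol": 1e-6})
    h = float(res.x)
    # compare against the OLS boundary explicitly
    if negll(0.0) <= res.fun:
        h = 0.0
    w = h * lam + (1.0 - h)
    sw = 1.0 / np.sqrt(w)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    s2 = float(r @ r) / n
    return MixedModelFit(
        sigma_g2=h * s2, sigma_e2=(1.0 - h) * s2, beta=beta,
        loglik=-negll(h), h2=h, eigvals=lam, eigvecs=U,
    )


def heritability(y: np.ndarray, covariates: np.ndarray,
                 kinship: KinshipMatrix | np.ndarray) -> float:
    """Narrow-sense heritability: additive genetic variance over total."""
    return fit_null(y, covariates, kinship).h2


@dataclass
class ScanResult:
    """Per-locus scan statistics and coefficient estimates."""

    model: str
    table: pd.DataFrame             # locus, chr, bp, lod, neglog10p
    coefficients: np.ndarray        # (n_loci, n_locus_terms)
    df: int

    @property
    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy(float)

    def peak(self) -> pd.Series:
        return self.table.iloc[int(np.argmax(self.lod))]


def _whiten(y, X_cov, fit: MixedModelFit | None):
    if fit is None or fit.eigvecs is None:
        return y.copy(), X_cov.copy(), None
    sw = 1.0 / np.sqrt(fit.weights)
    U = fit.eigvecs
    return (U.T @ y) * sw, (U.T @ X_cov) * sw[:, None], (U, sw)


def _batched_lod(yw: np.ndarray, Xw_cov: np.ndarray, G: np.ndarray):
    """LOD and locus coefficients for a stack of locus designs.

    ``G`` is (n, L, q) of locus predictors, already whitened.  Rank
    deficiency (aliased or constant predictors) is handled by minimum-norm
    solutions, so a locus adding no signal gets LOD = 0.
    """
    n, L, q = G.shape
    beta0, *_ = np.linalg.lstsq(Xw_cov, yw, rcond=None)
    r0 = yw - Xw_cov @ beta0
    rss0 = float(r0 @ r0)

    p0 = Xw_cov.shape[1]
    p = p0 + q
    A = np.empty((L, p, p))
    C = Xw_cov.T @ Xw_cov
    A[:, :p0, :p0] = C
    cross = np.einsum("np,nlq->lpq", Xw_cov, G)
    A[:, :p0, p0:] = cross
    A[:, p0:, :p0] = cross.transpose(0, 2, 1)
    A[:, p0:, p0:] = np.einsum("nlq,nlr->lqr", G, G)
    b = np.empty((L, p))
    b[:, :p0] = Xw_cov.T @ yw
    b[:, p0:] = np.einsum("nlq,n->lq", G, yw)
    Ainv = np.linalg.pinv(A, hermitian=True, rcond=1e-10)
    coef = np.einsum("lpq,lq->lp", Ainv, b)
    rss1 = float(yw @ yw) - np.einsum("lp,lp->l", coef, b)
    rss1 = np.maximum(rss1, 1e-300)
    lod = 0.5 * n * np.log10(np.maximum(rss0 / rss1, 1.0))
    return lod, coef[:, p0:], rss0, rss1


def _lod_to_neglog10p(lod: np.ndarray, df: int) -> np.ndarray:
    lr = 2.0 * LN10 * np.asarray(lod, float)
    return -stats.chi2.logsf(lr, df) / LN10


def scan(model: str, probs: DiplotypeProbs | np.ndarray, space: DiplotypeStateSpace,
         map: MarkerMap, pheno: PhenotypeTable | np.ndarray,
         kinship=None, covariates=(), loco: bool = False,
         sdp: SdpTable | None = None) -> ScanResult:
    """Genome scan under one of the three locus models.

    Parameters
    ----------
    model
        ``"full"``, ``"additive_haplotype"`` or ``"additive_snp"``.
    probs
        Diplotype posteriors (n, M, S); founder dosages and SNP dosages are
        derived internally as the model requires.
    kinship
        ``None`` (plain linear model), a ``KinshipMatrix``, or — with
        ``loco=True`` — a dict chromosome -> ``KinshipMatrix`` from
        ``loco_kinship``.
    sdp
        Founder SNP table; required for the additive SNP model.
    """
    if model not in MODEL_DF:
        raise ValueError(f"unknown model {model!r}")
    p = probs.probs if isinstance(probs, DiplotypeProbs) else np.asarray(probs, float)
    if isinstance(pheno, PhenotypeTable):
        y = pheno.y
        X_cov = pheno.design_matrix(covariates)
    else:
        y = np.asarray(pheno, float)
        X_cov = np.ones((len(y), 1))
        if covariates is not None and len(covariates) and isinstance(covariates, np.ndarray):
            X_cov = np.column_stack([X_cov, covariates])

    if model == "additive_snp":
        if sdp is None:
            raise ValueError("the additive SNP model requires a founder SNP table")
        return _scan_snp(p, space, map, y, X_cov, kinship, loco, sdp)

    G_all = p if model == "full" else dosage_from_probs(p, space)
    df = MODEL_DF[model]

    chroms = map.chromosomes
    rows, coefs = [], []
    shared_fit = None
    if kinship is not None and not loco:
        shared_fit = _null_for_chrom(y, X_cov, kinship, False, None)
    for chrom in chroms:
        sl = map.chrom_slice(chrom)
        fit = shared_fit if not loco else _null_for_chrom(y, X_cov, kinship, loco, chrom)
        yw, Xw, rot = _whiten(y, X_cov, fit)
        Gc = G_all[:, sl]
        if rot is not None:
            U, sw = rot
            n = len(y)
            Gc = np.einsum("ab,blq->alq", U.T, Gc) * sw[:, None, None]
        lod, coef, *_ = _batched_lod(yw, Xw, Gc)
        sub = map.table.iloc[sl]
        for k in range(len(sub)):
            rows.append((sub.iloc[k]["marker"], chrom, int(sub.iloc[k]["bp"]),
                         float(lod[k])))
        coefs.append(coef)
    tab = pd.DataFrame(rows, columns=["locus", "chr", "bp", "lod"])
    tab["neglog10p"] = _lod_to_neglog10p(tab["lod"].to_numpy(), df)
    return ScanResult(model, tab, np.vstack(coefs), df)


def _null_for_chrom(y, X_cov, kinship, loco, chrom):
    if kinship is None:
        return None
    if loco:
        if not isinstance(kinship, dict):
            raise ValueError("loco=True requires a chromosome->kinship mapping")
        return fit_null(y, X_cov, kinship[chrom])
    if isinstance(kinship, dict):
        raise ValueError("pass loco=True to use per-chromosome kinship")
    return fit_null(y, X_cov, kinship)


def _scan_snp(p, space, map, y, X_cov, kinship, loco, sdp: SdpTable) -> ScanResult:
    group_id, rep = collapse_sdp(map, sdp)
    dos = dosage_from_probs(p, space)  # (n, M, F)
    Gind = sdp.indicator()
    mono = sdp.monomorphic
    rows, coefs = [], []
    rep_chrom = sdp.chrom[rep]
    shared_fit = None
    if kinship is not None and not loco:
        shared_fit = _null_for_chrom(y, X_cov, kinship, False, None)
    for chrom in map.chromosomes:
        take = np.flatnonzero(rep_chrom == chrom)
        if take.size == 0:
            continue
        snp_idx = rep[take]
        fit = shared_fit if not loco else _null_for_chrom(y, X_cov, kinship, loco, chrom)
        yw, Xw, rot = _whiten(y, X_cov, fit)
        # founder dosage at each representative SNP: mean of flanking markers
        davg = interval_average(dos, map, chrom, sdp.bp[snp_idx])
        if davg.ndim == 2:
            davg = davg[:, None, :]
        g = np.einsum("nlf,lf->nl", davg, Gind[snp_idx])[:, :, None]
        g = np.clip(g, 0.0, 2.0)
        g[:, mono[snp_idx], :] = 0.0  # monomorphic: no test, LOD 0
        if rot is not None:
            U, sw = rot
            g = np.einsum("ab,blq->alq", U.T, g) * sw[:, None, None]
        lod, coef, *_ = _batched_lod(yw, Xw, g)
        for k, si in enumerate(snp_idx):
            rows.append((str(sdp.snp_id[si]), chrom, int(sdp.bp[si]), float(lod[k]),
                         int(take[k])))
        coefs.append(coef)
    tab = pd.DataFrame(rows, columns=["locus", "chr", "bp", "lod", "group"])
    tab["neglog10p"] = _lod_to_neglog10p(tab["lod"].to_numpy(), 1)
    res = ScanResult("additive_snp", tab, np.vstack(coefs), 1)
    res.group_of_snp = group_id
    return res


def founder_effects(result: ScanResult, locus_index: int) -> np.ndarray:
    """Centered founder coefficients at one locus of an additive scan.

    Coefficients are re-expressed with mean zero across founders, the
    convention used for allele-effect plots; centering is idempotent.
    """
    if result.model != "additive_haplotype":
        raise ValueError("founder effects require the additive haplotype model")
    beta = result.coefficients[locus_index]
    return beta - beta.mean()
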