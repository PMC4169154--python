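"""Power and type-I-error simulation studies.

Reproduces, at configurable (reduced) scale, the QTL detection power study:
genomes are drawn from a simulated generation-8 outbred pool, a biallelic
QTL (minor allele carried by 1-4 founders) is planted at a random autosomal
marker, and the phenotype is the QTL term (+effect / -effect on the two
homozygote classes, 0 for heterozygotes) on a background of a
kinship-structured polygenic component plus iid Gaussian error.  The two
background components contribute equally to a total background variance of
one; with that normalization the reference simulation cell (n = 600, minor
allele in 2 of 8 founders, effect 0.5 SD) explains ~9% of the phenotypic
variance, reproducing the published power study's variance bookkeeping.

Scans use the leave-one-chromosome-out (LOCO) kinship-adjusted mixed model.
Genome-wide LOD thresholds are calibrated once per sample size and locus
model from null scans of iid N(0,1) phenotypes with a plain linear model,
and a replicate counts as detected when its maximum LOD clears the
threshold within 5 Mb of the true locus.  The type-I study scans iid
Gaussian phenotypes with the kinship-adjusted additive haplotype model and
reports the fraction of replicates with any autosomal LOD above the same
threshold.

All three locus models (additive haplotype, additive SNP, full 36-state)
can be evaluated on shared replicates, reusing the per-replicate LOCO
eigendecompositions — the dominant cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosage import SdpTable
from .genome import DiplotypeStateSpace, FounderPanel, MarkerMap
from .kinship import kinship_from_dosage
from .scan import _batched_lod, fit_null
from .significance import _orth_basis
from .simulate import BreedingConfig, breed_do, default_marker_map

WINDOW_BP = 5_000_000  # detection window around the true locus

#: background variance split: polygenic + iid error, total 1
BG_POLYGENIC_VAR = 0.5
BG_ERROR_VAR = 0.5


@dataclass
class PowerGridConfig:
    """Full-study grid; defaults mirror the published design, scaled down."""

    sample_sizes: tuple = (200, 400, 600, 800, 1000)
    mafs: tuple = (1, 2, 3, 4)
    effects: tuple = (0.125, 0.25, 0.375, 0.5, 0.625, 0.75, 1.0)
    n_replicates: int = 200
    n_null: int = 300
    alpha: float = 0.05
    window_bp: int = WINDOW_BP
    n_markers: int = 500


class GenomePool:
    """Simulated G8 genomes shared by all replicates of a study.

    Holds true diplotype states and founder dosages at the markers, the
    pool-wide kinship matrix, per-chromosome partial kinship sums (so LOCO
    kinship for any sample subset is a cheap subtraction), and an optional
    founder SNP table for the additive SNP model.
    """

    def __init__(self, map: MarkerMap, space: DiplotypeStateSpace,
                 states: np.ndarray, dosages: np.ndarray,
                 sdp: SdpTable | None = None):
        self.map = map
        self.space = space
        self.states = states
        self.dosages = dosages
        self.sdp = sdp
        self.chrom_of_marker = map.table["chr"].to_numpy()
        dn = dosages / np.sqrt((dosages**2).sum(axis=2))[..., None]
        n = dn.shape[0]
        self._chrom_sums = {}
        for c in map.chromosomes:
            sel = self.chrom_of_marker == c
            flat = dn[:, sel].reshape(n, -1)
            self._chrom_sums[c] = flat @ flat.T
        total = sum(self._chrom_sums.values())
        self.kinship = total / map.n_markers
        np.fill_diagonal(self.kinship, 1.0)
        self._total_sum = total
        if sdp is not None:
            self._snp_marker_idx = _snp_marker_index(map, sdp)

    @property
    def n_pool(self) -> int:
        return self.states.shape[0]

    def loco_kinship(self, chrom, idx: np.ndarray) -> np.ndarray:
        """Kinship of the subset ``idx`` excluding chromosome ``chrom``."""
        sel = self.chrom_of_marker == chrom
        Mc = int(sel.sum())
        K = (self._total_sum - self._chrom_sums[chrom])[np.ix_(idx, idx)]
        K = K / (self.map.n_markers - Mc)
        np.fill_diagonal(K, 1.0)
        return K


def make_genome_pool(n_pool: int = 1100, n_markers: int = 500,
                     n_pairs: int = 175, generations: int = 8,
                     seed=None, with_snps: bool = True) -> GenomePool:
    """Breed a G8 pool and precompute dosages and kinship structure."""
    rng = np.random.default_rng(seed)
    map = default_marker_map(n_markers)
    panel = FounderPanel()
    space = DiplotypeStateSpace(panel)
    pop = breed_do(BreedingConfig(n_pairs, generations, n_final=n_pool), map, panel, rng)
    states = pop.state_indices(space)
    dosages = pop.dosages(space)
    sdp = marker_sdp_table(map, rng=rng) if with_snps else None
    return GenomePool(map, space, states, dosages, sdp)


def marker_sdp_table(map: MarkerMap, mafs=(1, 2, 3, 4), rng=None,
                     n_founders: int = 8) -> SdpTable:
    """One SNP per marker per minor-allele count, placed at the marker.

    Emulates a dense imputed SNP set: at every marker, one candidate SNP for
    each minor-allele founder count, with the carrier set drawn at random.
    The causal SNP of a power replicate is drawn from this table so the scan
    always tests the causal strain distribution pattern (the best case, as
    in a fully imputed genome).
    """
    rng = np.random.default_rng(rng)
    ids, chroms, bps, pats = [], [], [], []
    t = map.table
    full = (1 << n_founders) - 1
    for j in range(len(t)):
        for m in mafs:
            alt = rng.choice(n_founders, size=m, replace=False)
            mask = 0
            for a in alt:
                mask |= 1 << int(a)
            ids.append(f"{t.loc[j, 'marker']}_maf{m}")
            chroms.append(t.loc[j, "chr"])
            bps.append(int(t.loc[j, "bp"]))
            pats.append(full & ~mask)
    return SdpTable(np.array(ids), np.array(chroms, dtype=object),
                    np.array(bps, np.int64), np.array(pats, np.uint32),
                    n_founders=n_founders)


def effect_for_variance_share(share: float, maf: int) -> float:
    """Homozygote effect size giving an expected QTL variance share.

    Under random mating with minor-allele frequency p = maf/8, the
    +a/0/-a genotype coding has variance 2 p (1-p) a^2; the background
    variance is 1, so share v solves 2 p (1-p) a^2 = v / (1 - v).
    """
    if not 0.0 < share < 1.0:
        raise ValueError("variance share must lie in (0, 1)")
    p = maf / 8.0
    return float(np.sqrt(share / (1.0 - share) / (2.0 * p * (1.0 - p))))


# ---------------------------------------------------------------------------
# Internal batched scans on true genotypes
# ---------------------------------------------------------------------------

def _whiten_predictors(G: np.ndarray, U: np.ndarray, sw: np.ndarray) -> np.ndarray:
    n, L, q = G.shape
    return (U.T @ G.reshape(n, L * q)).reshape(n, L, q) * sw[:, None, None]


def _predictor_lod(G: np.ndarray, y: np.ndarray, K: np.ndarray | None) -> np.ndarray:
    """(L,) LOD curve for (n, L, q) predictors, single kinship matrix."""
    n = len(y)
    X_cov = np.ones((n, 1))
    if K is None:
        yw, Xw = y, X_cov
        Gw = G
    else:
        fit = fit_null(y, X_cov, K)
        sw = 1.0 / np.sqrt(fit.weights)
        U = fit.eigvecs
        yw = (U.T @ y) * sw
        Xw = (U.T @ X_cov) * sw[:, None]
        Gw = _whiten_predictors(G, U, sw)
    lod, *_ = _batched_lod(yw, Xw, Gw)
    return lod


def _loco_lod(pool: GenomePool, idx: np.ndarray, chols: dict,
              G: np.ndarray, loc_chrom: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOD curve with LOCO kinship via per-chromosome Cholesky whitening.

    ``chols`` maps chromosome -> lower Cholesky factor of
    h * K_loco + (1 - h) * I for the phenotype's heritability h (estimated
    once on the global kinship); whitening is a triangular solve.
    """
    from scipy.linalg import solve_triangular

    n = len(y)
    X_cov = np.ones((n, 1))
    lod = np.empty(G.shape[1])
    for chrom, L in chols.items():
        sel = loc_chrom == chrom
        if not sel.any():
            continue
        Gc = G[:, sel]
        q = Gc.shape[2]
        if L is None:  # h == 0: ordinary least squares
            yw, Xw, Gw = y, X_cov, Gc
        else:
            block = np.concatenate(
                [y[:, None], X_cov, Gc.reshape(n, -1)], axis=1)
            white = solve_triangular(L, block, lower=True, check_finite=False)
            yw = white[:, 0]
            Xw = white[:, 1:2]
            Gw = white[:, 2:].reshape(n, -1, q)
        lod[sel], *_ = _batched_lod(yw, Xw, Gw)
    return lod


def _loco_chols(pool: GenomePool, idx: np.ndarray, h: float) -> dict:
    """Per-chromosome Cholesky factors of the LOCO mixed-model covariance."""
    n = len(idx)
    if h <= 1e-8:
        return {c: None for c in pool.map.chromosomes}
    eye = np.eye(n)
    out = {}
    for c in pool.map.chromosomes:
        W = h * pool.loco_kinship(c, idx) + (1.0 - h) * eye
        out[c] = np.linalg.cholesky(W + 1e-10 * eye)
    return out


def _null_max_lods_pred(G: np.ndarray, n_null: int, rng) -> np.ndarray:
    """Max-LOD nulls for (n, L, q) predictors, plain linear model, batched."""
    n, L, q = G.shape
    Y = rng.standard_normal((n, n_null))
    Yc = Y - Y.mean(axis=0, keepdims=True)
    tss = (Yc**2).sum(axis=0)
    best = np.zeros(n_null)
    ones = np.ones((n, 1))
    for k in range(L):
        Q = _orth_basis(np.column_stack([ones, G[:, k]]))
        proj = Q.T @ Yc
        rss1 = np.maximum(tss - (proj**2).sum(axis=0), 1e-300)
        lod = 0.5 * n * np.log10(np.maximum(tss / rss1, 1.0))
        np.maximum(best, lod, out=best)
    return best


def _model_predictors(pool: GenomePool, idx: np.ndarray, model: str):
    """Locus predictors and locus chrom/bp arrays for a drawn sample."""
    t = pool.map.table
    if model == "additive_haplotype":
        G = pool.dosages[idx]
        return G, t["chr"].to_numpy(), t["bp"].to_numpy(np.int64)
    if model == "full":
        S = pool.space.n_states
        st = pool.states[idx]
        n, M = st.shape
        G = np.zeros((n, M, S))
        np.put_along_axis(G, st[:, :, None].astype(np.int64), 1.0, axis=2)
        return G, t["chr"].to_numpy(), t["bp"].to_numpy(np.int64)
    if model == "additive_snp":
        sdp = pool.sdp
        if sdp is None:
            raise ValueError("pool was built without a founder SNP table")
        d_at = pool.dosages[idx][:, pool._snp_marker_idx, :]   # (n, nsnp, F)
        g = np.einsum("nsf,sf->ns", d_at, sdp.indicator())[:, :, None]
        return g, sdp.chrom, sdp.bp
    raise ValueError(f"unknown model {model!r}")


def _snp_marker_index(map: MarkerMap, sdp: SdpTable) -> np.ndarray:
    """Nearest-marker index per SNP (SNPs of the study table sit at markers)."""
    idx = np.empty(len(sdp), dtype=np.int64)
    bp_all = map.bp()
    chr_all = map.table["chr"].to_numpy()
    for chrom in map.chromosomes:
        mask = sdp.chrom == chrom
        if not mask.any():
            continue
        rows = np.flatnonzero(chr_all == chrom)
        pos = bp_all[rows]
        j = np.clip(np.searchsorted(pos, sdp.bp[mask]), 0, len(pos) - 1)
        jm = np.clip(j - 1, 0, len(pos) - 1)
        nearer = np.where(np.abs(pos[j] - sdp.bp[mask])
                          <= np.abs(pos[jm] - sdp.bp[mask]), j, jm)
        idx[mask] = rows[nearer]
    return idx


def calibrate_threshold(pool: GenomePool, n: int, model: str = "additive_haplotype",
                        n_null: int = 300, alpha: float = 0.05, seed=None) -> float:
    """Genome-wide LOD threshold for a sample size: quantile of null maxima
    from plain linear-model scans of iid N(0,1) phenotypes."""
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool.n_pool, size=n, replace=False)
    G, _, _ = _model_predictors(pool, idx, model)
    maxima = _null_max_lods_pred(G, n_null, rng)
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


def _popcount(patterns: np.ndarray) -> np.ndarray:
    v = patterns.astype(np.uint32)
    out = np.zeros_like(v)
    for b in range(32):
        out += (v >> b) & 1
    return out


@dataclass
class StudyResult:
    """Shared-replicate simulation study over one (n, MAF, effect) cell."""

    n: int
    maf: int
    effect: float
    n_replicates: int
    thresholds: dict
    detected: dict          # model -> bool array (n_replicates,)
    varexp: np.ndarray
    type1_hits: np.ndarray | None = None
    interval_width_bp: np.ndarray | None = None

    def power(self, model: str = "additive_haplotype") -> float:
        return float(self.detected[model].mean())

    @property
    def type1(self) -> float | None:
        if self.type1_hits is None:
            return None
        return float(self.type1_hits.mean())

    @property
    def mean_varexp(self) -> float:
        return float(self.varexp.mean())


def run_sim_study(pool: GenomePool, n: int, maf: int, effect: float,
                  n_replicates: int = 200,
                  models=("additive_haplotype",),
                  thresholds: dict | None = None, n_null: int = 300,
                  alpha: float = 0.05, window_bp: int = WINDOW_BP,
                  with_type1: bool = False, seed=None,
                  polygenic_var: float = BG_POLYGENIC_VAR,
                  error_var: float = BG_ERROR_VAR,
                  track_intervals: bool = False) -> StudyResult:
    """Power (and optionally type-I) estimates on shared replicates.

    Per replicate: draw ``n`` genomes without replacement, plant one QTL at
    a random autosomal marker (for the additive SNP model, at a random SNP
    of the requested minor-founder count), build the phenotype, scan every
    requested model with LOCO kinship, and score detection against each
    model's genome-wide threshold.  With ``with_type1`` an independent iid
    N(0,1) phenotype is scanned in the same replicate (reusing the LOCO
    eigendecompositions) and any autosomal exceedance is counted.
    """
    rng = np.random.default_rng(seed)
    if thresholds is None:
        thresholds = {}
    for m in models:
        if m not in thresholds:
            thresholds[m] = calibrate_threshold(
                pool, n, m, n_null, alpha, rng.integers(2**31 - 1))
    F = pool.space.panel.n_founders
    t = pool.map.table
    detected = {m: np.zeros(n_replicates, dtype=bool) for m in models}
    varexp = np.zeros(n_replicates)
    type1_hits = np.zeros(n_replicates, dtype=bool) if with_type1 else None
    widths = np.zeros(n_replicates) if track_intervals else None
    snp_cand = None
    if "additive_snp" in models:
        snp_cand = np.flatnonzero(F - _popcount(pool.sdp.patterns) == maf)

    for r in range(n_replicates):
        idx = rng.choice(pool.n_pool, size=n, replace=False)
        # QTL: random autosomal marker; for the SNP model the causal variant
        # is one of the table's SNPs with the requested minor-founder count,
        # so its location and carrier set drive all models consistently.
        if snp_cand is not None:
            snp = int(rng.choice(snp_cand))
            minor = np.flatnonzero(1 - ((pool.sdp.patterns[snp] >> np.arange(F)) & 1))
            marker = int(pool._snp_marker_idx[snp])
        else:
            marker = int(rng.integers(len(t)))
            minor = rng.choice(F, size=maf, replace=False)
        qtl_bp = int(t.loc[marker, "bp"])
        qtl_chr = t.loc[marker, "chr"]

        minor_dose = pool.dosages[idx, marker][:, minor].sum(axis=1)
        qtl_term = np.where(minor_dose >= 2 - 1e-9, effect,
                            np.where(minor_dose <= 1e-9, -effect, 0.0))
        K = pool.kinship[np.ix_(idx, idx)]
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        y = (qtl_term
             + np.sqrt(polygenic_var) * (L @ rng.standard_normal(n))
             + np.sqrt(error_var) * rng.standard_normal(n))
        varexp[r] = qtl_term.var() / y.var()

        eigG = np.linalg.eigh(K)
        h = fit_null(y, np.ones((n, 1)), None, eig=eigG).h2
        chols = _loco_chols(pool, idx, h)
        for m in models:
            G, loc_chr, loc_bp = _model_predictors(pool, idx, m)
            lod = _loco_lod(pool, idx, chols, G, loc_chr, y)
            b = int(np.argmax(lod))
            if (lod[b] > thresholds[m] and loc_chr[b] == qtl_chr
                    and abs(int(loc_bp[b]) - qtl_bp) <= window_bp):
                detected[m][r] = True
            if track_intervals and m == "additive_haplotype":
                from .significance import credible_interval
                sel = loc_chr == qtl_chr
                ci = credible_interval(lod[sel], loc_bp[sel], chrom=qtl_chr)
                widths[r] = ci.width_bp
        if with_type1:
            y0 = rng.standard_normal(n)
            h0 = fit_null(y0, np.ones((n, 1)), None, eig=eigG).h2
            chols0 = _loco_chols(pool, idx, h0)
            G, loc_chr, _ = _model_predictors(pool, idx, "additive_haplotype")
            lod0 = _loco_lod(pool, idx, chols0, G, loc_chr, y0)
            type1_hits[r] = lod0.max() > thresholds.get(
                "additive_haplotype", next(iter(thresholds.values())))
    return StudyResult(n, maf, effect, n_replicates, dict(thresholds),
                       detected, varexp, type1_hits, widths)


# -- spec-level convenience wrappers ----------------------------------------

@dataclass
class PowerResult:
    """One cell of the power grid."""

    n: int
    maf: int
    effect: float
    model: str
    power: float
    mean_varexp: float
    threshold: float
    n_replicates: int
    detected: np.ndarray = field(repr=False, default=None)
    varexp: np.ndarray = field(repr=False, default=None)


def run_power_cell(pool: GenomePool, n: int, maf: int, effect: float,
                   n_replicates: int = 200, model: str = "additive_haplotype",
                   threshold: float | None = None, n_null: int = 300,
                   alpha: float = 0.05, window_bp: int = WINDOW_BP,
                   seed=None) -> PowerResult:
    """Estimate detection power for one (n, MAF, effect) cell."""
    thresholds = None if threshold is None else {model: threshold}
    study = run_sim_study(pool, n, maf, effect, n_replicates, (model,),
                          thresholds, n_null, alpha, window_bp, seed=seed)
    return PowerResult(n, maf, effect, model, study.power(model),
                       study.mean_varexp, study.thresholds[model],
                       n_replicates, study.detected[model], study.varexp)


def run_type1_cell(pool: GenomePool, n: int, n_replicates: int = 200,
                   threshold: float | None = None, n_null: int = 300,
                   alpha: float = 0.05, seed=None,
                   model: str = "additive_haplotype") -> float:
    """Genome-wide type I error of the kinship-adjusted scan at the threshold.

    Null phenotypes are iid standard normal; the estimate is the fraction of
    replicates whose autosomal maximum LOD exceeds the threshold.
    """
    rng = np.random.default_rng(seed)
    if threshold is None:
        threshold = calibrate_threshold(pool, n, model, n_null, alpha,
                                        rng.integers(2**31 - 1))
    hits = 0
    for r in range(n_replicates):
        idx = rng.choice(pool.n_pool, size=n, replace=False)
        y = rng.standard_normal(n)
        eigG = np.linalg.eigh(pool.kinship[np.ix_(idx, idx)])
        h = fit_null(y, np.ones((n, 1)), None, eig=eigG).h2
        chols = _loco_chols(pool, idx, h)
        G, loc_chr, _ = _model_predictors(pool, idx, model)
        lod = _loco_lod(pool, idx, chols, G, loc_chr, y)
        if lod.max() > threshold:
            hits += 1
    return hits / n_replicates


def power_curve(results: list):
    """Logistic fit of replicate-level detection vs. percent variance explained.

    Pools all replicates of the given cells (typically one sample size) and
    fits detection ~ logistic(% variance explained).  Returns the fitted
    statsmodels result, or ``None`` for degenerate all-detected /
    none-detected inputs; evaluate with ``predict_power``.
    """
    import statsmodels.api as sm

    det = np.concatenate([np.asarray(r.detected, float) if not isinstance(r, StudyResult)
                          else r.detected["additive_haplotype"].astype(float)
                          for r in results])
    vx = np.concatenate([100.0 * r.varexp for r in results])
    if det.min() == det.max():
        return None
    X = sm.add_constant(vx)
    return sm.GLM(det, X, family=sm.families.Binomial()).fit()


def predict_power(fit, varexp_percent: float) -> float:
    return float(fit.predict([1.0, varexp_percent])[0])
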