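"""Diplotype reconstruction: preprocessing, 36-state HMM, EM, phasing.

The hidden state at marker j of animal i is its founder diplotype; the chain
over markers is governed by a transition model derived from the genetic map
and the outbreeding generation, and observations enter through one of two
emission models:

* a multinomial over the four genotype-call outcomes {A, H, B, N} per state
  per marker ("no call" is an informative outcome, never missing data);
* a product of two univariate Gaussians on the polar-transformed intensity
  coordinates (theta, rho), four parameters per state per marker.

Emission parameters are fit by EM with the transition model held fixed;
the E-step is a scaled forward-backward pass per sample per chromosome, the
M-step pools posterior-weighted sufficient statistics across samples at each
marker.  Posterior diplotype probabilities p_ij(s) are the primary output;
marginal (argmax) reconstructions, parsimony phasing and recombination
counting are derived from them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import (
    DiplotypeProbs,
    DiplotypeStateSpace,
    GenotypeCalls,
    IntensityData,
    MarkerMap,
    PhasedReconstruction,
    expected_genotype,
)

VAR_FLOOR = 1e-4      # emission variance floor (prevents cluster collapse)
PROB_FLOOR = 1e-4     # multinomial floor before renormalization


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(reference: IntensityData, target: IntensityData) -> IntensityData:
    """Map reference-sample intensities onto the target cohort's quantiles.

    At each marker and channel, each reference sample's value is replaced by
    the target cohort's empirical quantile at the reference value's rank
    (linear interpolation between order statistics).  Used to place founder
    and F1 reference samples on the same intensity scale as the study cohort.
    """
    if reference.shape[1] != target.shape[1]:
        raise ValueError("reference and target must cover the same markers")
    if target.shape[0] < 2 or reference.shape[0] < 2:
        raise ValueError("need at least 2 samples per cohort")

    def _one(ref: np.ndarray, tgt: np.ndarray) -> np.ndarray:
        out = np.empty_like(ref)
        nr, nt = ref.shape[0], tgt.shape[0]
        p_ref = (np.arange(nr) + 0.5) / nr
        p_tgt = (np.arange(nt) + 0.5) / nt
        for j in range(ref.shape[1]):
            order = np.argsort(ref[:, j], kind="stable")
            mapped = np.interp(p_ref, p_tgt, np.sort(tgt[:, j]))
            out[order, j] = mapped
        return out

    return IntensityData(reference.samples, _one(reference.x, target.x),
                         _one(reference.y, target.y))


def polar_transform(x, y):
    """(X, Y) intensities -> (theta, rho) with theta in [0, 1] over the quadrant.

    theta = (2/pi) * atan2(Y, X); rho = sqrt(X^2 + Y^2).  The undefined angle
    at the origin is assigned theta = 0.5.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho = np.hypot(x, y)
    with np.errstate(invalid="ignore"):
        theta = (2.0 / np.pi) * np.arctan2(y, x)
    theta = np.where(rho == 0.0, 0.5, theta)
    return theta, rho


def polar_intensities(data: IntensityData) -> tuple[np.ndarray, np.ndarray]:
    return polar_transform(data.x, data.y)


# ---------------------------------------------------------------------------
# Transition model
# ---------------------------------------------------------------------------

@dataclass
class TransitionModel:
    """Per-interval diplotype transition matrices for one or more chromosomes.

    The diplotype chain is the product of two independent single-haplotype
    chains.  Per haplotype, over genetic distance d Morgans the ancestry
    switches with probability 1 - exp(-lam * d) and then lands uniformly on
    the F founders; lam grows linearly with outbreeding generation G,
    calibrated so the expected number of autosomal ancestry switches gained
    per generation matches ``events_per_generation`` over the supplied map.
    """

    space: DiplotypeStateSpace
    matrices: dict  # chrom -> (n_markers-1, S, S)
    G: int
    lam: float

    def chrom(self, chrom) -> np.ndarray:
        return self.matrices[chrom]


#: theoretical autosomal ancestry-switch accumulation per generation for the
#: standard DO design (depends on the founders' funnel history; exposed as a
#: calibration constant, not hard-coded downstream).
DEFAULT_EVENTS_PER_GENERATION = 23.9

#: total autosomal genetic length (Morgans) the event rate refers to; the
#: per-haplotype switch rate is per Morgan, so it must not depend on how much
#: of the genome a particular marker map covers.
GENOME_LENGTH_MORGANS = 14.41


def haplotype_transition(F: int, lam: float, d_morgans: float) -> np.ndarray:
    """Single-haplotype F x F transition over genetic distance d (Morgans)."""
    stay = np.exp(-lam * d_morgans)
    T = np.full((F, F), (1.0 - stay) / F)
    T[np.diag_indices(F)] += stay
    return T


def diplotype_transition(space: DiplotypeStateSpace, T_hap: np.ndarray) -> np.ndarray:
    """Combine two independent haplotype chains into the unordered-pair chain."""
    pairs = space.pairs
    S = len(pairs)
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    c = a[None, :].repeat(S, 0)
    d = b[None, :].repeat(S, 0)
    A = a[:, None]
    B = b[:, None]
    P = T_hap[A, c] * T_hap[B, d]
    het_target = (c != d)
    P = np.where(het_target, P + T_hap[A, d] * T_hap[B, c], P)
    return P


def build_transition(map: MarkerMap, G: int, space: DiplotypeStateSpace,
                     events_per_generation: float = DEFAULT_EVENTS_PER_GENERATION,
                     genome_length_morgans: float = GENOME_LENGTH_MORGANS,
                     ) -> TransitionModel:
    """Transition model from the genetic map and outbreeding generation.

    The per-haplotype ancestry-switch rate is
    ``lam = G * events_per_generation / (2 * genome_length_morgans)`` per
    Morgan — a genome-wide density, deliberately independent of how much of
    the genome the supplied map covers.
    """
    if G < 1:
        raise ValueError("generation must be >= 1")
    # two haplotypes per genome: 2 * lam * L_genome = events accumulated
    lam = events_per_generation * G / (2.0 * genome_length_morgans)
    matrices = {}
    for chrom in map.chromosomes:
        cm = map.cM(chrom)
        d = np.diff(cm) / 100.0
        mats = np.empty((len(d), space.n_states, space.n_states))
        for k, dk in enumerate(d):
            if dk == 0:
                mats[k] = np.eye(space.n_states)
            else:
                mats[k] = diplotype_transition(
                    space, haplotype_transition(space.panel.n_founders, lam, dk)
                )
        matrices[chrom] = mats
    return TransitionModel(space, matrices, G, lam)


def equilibrium_distribution(space: DiplotypeStateSpace) -> np.ndarray:
    """Stationary diplotype distribution: 1/F^2 per homozygote, 2/F^2 per het."""
    F = space.panel.n_founders
    pi = np.where(space.is_homozygous, 1.0, 2.0) / F**2
    return pi


# ---------------------------------------------------------------------------
# Emission models
# ---------------------------------------------------------------------------

@dataclass
class GenotypeEmission:
    """Per-marker, per-state multinomial over the calls {A, H, B, N}."""

    probs: np.ndarray  # (M, S, 4)

    def __post_init__(self):
        p = np.asarray(self.probs, float)
        if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-8):
            raise ValueError("emission distributions must sum to 1")
        if (p <= 0).any():
            raise ValueError("emission probabilities must be strictly positive")
        self.probs = p

def genotype_emission_loglik(emission: "GenotypeEmission", calls: np.ndarray) -> np.ndarray:
    """(n, M, S) log P(call | state) — efficient gather without copies."""
    P = emission.probs  # (M, S, 4)
    n, M = calls.shape
    logP = np.log(P)  # (M, S, 4)
    out = logP.transpose(2, 0, 1)[calls.astype(np.int64), np.arange(M)[None, :], :]
    return out


def init_genotype_emission(founder_alleles: np.ndarray, space: DiplotypeStateSpace,
                           p_expected: float = 0.97) -> GenotypeEmission:
    """Initial multinomial: expected call at ``p_expected``, rest spread evenly."""
    geno = expected_genotype(founder_alleles, space)  # (M, S)
    M, S = geno.shape
    other = (1.0 - p_expected) / 3.0
    P = np.full((M, S, 4), other)
    idx0, idx1 = np.meshgrid(np.arange(M), np.arange(S), indexing="ij")
    P[idx0, idx1, geno.astype(np.int64)] = p_expected
    return GenotypeEmission(P)


@dataclass
class IntensityEmission:
    """Per-marker, per-state Gaussian parameters on (theta, rho)."""

    mu_theta: np.ndarray  # (M, S)
    var_theta: np.ndarray
    mu_rho: np.ndarray
    var_rho: np.ndarray

    def __post_init__(self):
        for v in (self.var_theta, self.var_rho):
            if (v < VAR_FLOOR * (1 - 1e-12)).any():
                raise ValueError("emission variances below the configured floor")


def intensity_emission_loglik(emission: IntensityEmission, theta: np.ndarray,
                              rho: np.ndarray) -> np.ndarray:
    """(n, M, S) log N(theta; mu_t, var_t) + log N(rho; mu_r, var_r)."""
    mt, vt = emission.mu_theta, emission.var_theta
    mr, vr = emission.mu_rho, emission.var_rho
    lt = -0.5 * (np.log(2 * np.pi * vt)[None] + (theta[..., None] - mt[None]) ** 2 / vt[None])
    lr = -0.5 * (np.log(2 * np.pi * vr)[None] + (rho[..., None] - mr[None]) ** 2 / vr[None])
    return lt + lr


def emission_loglik(model, obs, kind: str) -> np.ndarray:
    """Dispatch: log emission likelihood array (n, M, S) for either model."""
    if kind == "calls":
        return genotype_emission_loglik(model, obs)
    if kind == "intensity":
        theta, rho = obs
        return intensity_emission_loglik(model, theta, rho)
    raise ValueError(f"unknown emission kind {kind!r}")


# ---------------------------------------------------------------------------
# Cluster initialization for the intensity model
# ---------------------------------------------------------------------------

def init_clusters(ref_theta: np.ndarray, ref_rho: np.ndarray,
                  ref_states: np.ndarray,
                  cohort_theta: np.ndarray, cohort_rho: np.ndarray,
                  space: DiplotypeStateSpace,
                  max_clusters: int = 9, rng=None):
    """Initial per-state intensity parameters at one marker.

    Fits bivariate Gaussian mixtures (diagonal covariance, on theta/rho) to
    the pooled reference + cohort samples for k = 1..max_clusters, selects k
    by BIC, then assigns each diplotype state to the cluster nearest the mean
    position of its reference samples (founders and F1s of known diplotype).
    States without reference samples inherit the cluster of the nearest
    reference state center.

    Returns ``(assignment, emission)``: per-state cluster index and an
    ``IntensityEmission`` for this single marker (arrays of shape (1, S)).
    """
    from sklearn.mixture import GaussianMixture

    pts = np.column_stack([
        np.concatenate([ref_theta, cohort_theta]),
        np.concatenate([ref_rho, cohort_rho]),
    ])
    best = None
    best_bic = np.inf
    seed = int(np.random.default_rng(rng).integers(2**31 - 1))
    kmax = min(max_clusters, len(pts))
    for k in range(1, kmax + 1):
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             random_state=seed, n_init=1, reg_covar=VAR_FLOOR)
        gm.fit(pts)
        bic = gm.bic(pts)
        if bic < best_bic - 1e-9:
            best_bic, best = bic, gm
    centers = best.means_          # (k, 2)
    covs = best.covariances_       # (k, 2)

    S = space.n_states
    state_pos = np.full((S, 2), np.nan)
    for s in range(S):
        mask = ref_states == s
        if mask.any():
            state_pos[s] = [ref_theta[mask].mean(), ref_rho[mask].mean()]
    known = ~np.isnan(state_pos[:, 0])
    if not known.any():
        raise ValueError("no reference samples with known diplotypes")
    missing = np.flatnonzero(~known)
    if missing.size:
        warnings.warn(f"{missing.size} states lack reference samples; "
                      "assigned to nearest reference-derived center")
        kn = np.flatnonzero(known)
        for s in missing:
            # nearest reference state by founder sharing, then its position
            share = (space.N[:, s][:, None] * space.N[:, kn]).sum(axis=0)
            state_pos[s] = state_pos[kn[np.argmax(share)]]
    d2 = ((state_pos[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    assignment = d2.argmin(axis=1)
    mu = centers[assignment]
    var = np.maximum(covs[assignment], VAR_FLOOR)
    emission = IntensityEmission(
        mu_theta=mu[None, :, 0], var_theta=var[None, :, 0],
        mu_rho=mu[None, :, 1], var_rho=var[None, :, 1],
    )
    return assignment, emission


def init_intensity_emission(ref: IntensityData, ref_states: np.ndarray,
                            cohort: IntensityData, space: DiplotypeStateSpace,
                            max_clusters: int = 9, rng=None) -> IntensityEmission:
    """Run per-marker BIC cluster initialization across all markers."""
    rt, rr = polar_intensities(ref)
    ct, cr = polar_intensities(cohort)
    M = ref.shape[1]
    S = space.n_states
    mu_t = np.empty((M, S)); va_t = np.empty((M, S))
    mu_r = np.empty((M, S)); va_r = np.empty((M, S))
    rng = np.random.default_rng(rng)
    for j in range(M):
        _, em = init_clusters(rt[:, j], rr[:, j], ref_states[:, j],
                              ct[:, j], cr[:, j], space, max_clusters, rng)
        mu_t[j], va_t[j] = em.mu_theta[0], em.var_theta[0]
        mu_r[j], va_r[j] = em.mu_rho[0], em.var_rho[0]
    return IntensityEmission(mu_t, va_t, mu_r, va_r)


# ---------------------------------------------------------------------------
# Forward-backward
# ---------------------------------------------------------------------------

def forward_backward(log_emission: np.ndarray, transitions: np.ndarray,
                     prior: np.ndarray):
    """Scaled forward-backward over one chromosome for a batch of samples.

    Parameters
    ----------
    log_emission
        (n, M, S) log emission likelihoods.
    transitions
        (M-1, S, S) transition matrices between adjacent markers.
    prior
        (S,) initial state distribution.

    Returns
    -------
    posterior : (n, M, S) diplotype probabilities, rows summing to 1.
    loglik : (n,) per-sample log-likelihood of the observations.
    """
    n, M, S = log_emission.shape
    if transitions.shape[0] != M - 1:
        raise ValueError("need one transition matrix per adjacent marker pair")
    # per-sample-marker max for stable exponentiation
    shift = log_emission.max(axis=2, keepdims=True)
    emis = np.exp(log_emission - shift)
    emis = np.maximum(emis, 1e-300)

    alpha = np.empty((n, M, S))
    c = np.empty((n, M))
    a = prior[None, :] * emis[:, 0]
    norm = a.sum(axis=1)
    bad = norm <= 0
    if bad.any():
        warnings.warn("all-zero emission row; applying numerical floor")
        a[bad] = 1.0 / S
        norm[bad] = 1.0
    c[:, 0] = norm
    alpha[:, 0] = a / norm[:, None]
    for j in range(1, M):
        a = (alpha[:, j - 1] @ transitions[j - 1]) * emis[:, j]
        norm = a.sum(axis=1)
        bad = norm <= 0
        if bad.any():
            a[bad] = 1.0 / S
            norm[bad] = 1.0
        c[:, j] = norm
        alpha[:, j] = a / norm[:, None]

    beta = np.empty((n, M, S))
    beta[:, M - 1] = 1.0
    for j in range(M - 2, -1, -1):
        b = (beta[:, j + 1] * emis[:, j + 1]) @ transitions[j].T
        beta[:, j] = b / c[:, j + 1][:, None]

    post = alpha * beta
    post /= post.sum(axis=2, keepdims=True)
    loglik = np.log(c).sum(axis=1) + shift[:, :, 0].sum(axis=1)
    return post, loglik


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

@dataclass
class EMState:
    """EM fit bookkeeping: parameter snapshot, LL trace, convergence flag."""

    emission: object
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _e_step(data, emission, kind, transition: TransitionModel, map: MarkerMap):
    """Posterior probabilities and total LL across all chromosomes."""
    space = transition.space
    prior = equilibrium_distribution(space)
    if kind == "calls":
        n, M = data.calls.shape
    else:
        theta, rho = data
        n, M = theta.shape
    post = np.empty((n, M, space.n_states))
    total_ll = 0.0
    for chrom in map.chromosomes:
        sl = map.chrom_slice(chrom)
        if kind == "calls":
            le = _slice_genotype_loglik(emission, data.calls, sl)
        else:
            le = intensity_emission_loglik(_slice_intensity(emission, sl),
                                           theta[:, sl], rho[:, sl])
        p, ll = forward_backward(le, transition.chrom(chrom), prior)
        post[:, sl] = p
        total_ll += ll.sum()
    return post, total_ll


def _slice_genotype_loglik(emission: GenotypeEmission, calls: np.ndarray, sl) -> np.ndarray:
    sub = GenotypeEmission.__new__(GenotypeEmission)
    sub.probs = emission.probs[sl]
    return genotype_emission_loglik(sub, calls[:, sl])


def _slice_intensity(emission: IntensityEmission, sl) -> IntensityEmission:
    sub = IntensityEmission.__new__(IntensityEmission)
    sub.mu_theta = emission.mu_theta[sl]
    sub.var_theta = emission.var_theta[sl]
    sub.mu_rho = emission.mu_rho[sl]
    sub.var_rho = emission.var_rho[sl]
    return sub


def _m_step_calls(post: np.ndarray, calls: np.ndarray, S: int) -> GenotypeEmission:
    n, M = calls.shape
    counts = np.zeros((M, S, 4))
    for c in range(4):
        mask = calls == c  # (n, M)
        counts[:, :, c] = np.einsum("nm,nms->ms", mask.astype(float), post)
    counts += PROB_FLOOR
    counts /= counts.sum(axis=-1, keepdims=True)
    return GenotypeEmission(counts)


def _m_step_intensity(post: np.ndarray, theta: np.ndarray, rho: np.ndarray,
                      old: IntensityEmission) -> IntensityEmission:
    w = post.sum(axis=0)  # (M, S)
    wsafe = np.maximum(w, 1e-12)
    mu_t = np.einsum("nms,nm->ms", post, theta) / wsafe
    mu_r = np.einsum("nms,nm->ms", post, rho) / wsafe
    va_t = np.einsum("nms,nm->ms", post, theta**2) / wsafe - mu_t**2
    va_r = np.einsum("nms,nm->ms", post, rho**2) / wsafe - mu_r**2
    # states with essentially no posterior mass keep their previous parameters
    empty = w < 1e-6
    mu_t[empty] = old.mu_theta[empty]
    mu_r[empty] = old.mu_rho[empty]
    va_t[empty] = old.var_theta[empty]
    va_r[empty] = old.var_rho[empty]
    return IntensityEmission(np.clip(mu_t, None, None), np.maximum(va_t, VAR_FLOOR),
                             mu_r, np.maximum(va_r, VAR_FLOOR))


def em_fit(data, map: MarkerMap, transition: TransitionModel, emission,
           tol: float = 1e-3, max_iter: int = 100):
    """Fit emission parameters by EM; transition parameters stay fixed.

    ``data`` is a ``GenotypeCalls`` (multinomial model) or a
    ``(theta, rho)`` array pair (intensity model).  Iterations stop when the
    log-likelihood changes by less than ``tol`` times the magnitude of the
    initial log-likelihood.

    Returns ``(EMState, DiplotypeProbs)``.
    """
    if isinstance(data, GenotypeCalls):
        kind = "calls"
        n = data.calls.shape[0]
        samples = data.samples
    else:
        kind = "intensity"
        n = data[0].shape[0]
        samples = [f"S{i:04d}" for i in range(n)]
    if n < 2:
        raise ValueError("EM requires at least 2 samples")
    if n < 100:
        warnings.warn("EM emission estimates are unreliable below ~100 samples")

    state = EMState(emission=emission)
    post = None
    ll0 = None
    prev_ll = -np.inf
    for it in range(max_iter):
        post, ll = _e_step(data, state.emission, kind, transition, map)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood in EM")
        state.loglik_trace.append(float(ll))
        state.n_iter = it + 1
        if ll0 is None:
            ll0 = ll
        elif abs(ll - prev_ll) < abs(ll0) * tol:
            state.converged = True
            break
        prev_ll = ll
        if kind == "calls":
            state.emission = _m_step_calls(post, data.calls, transition.space.n_states)
        else:
            theta, rho = data
            state.emission = _m_step_intensity(post, theta, rho, state.emission)
    return state, DiplotypeProbs(list(samples), post)


def reconstruct(data, map: MarkerMap, space: DiplotypeStateSpace, G: int,
                emission=None, founder_alleles=None, tol: float = 1e-3,
                max_iter: int = 100,
                events_per_generation: float = DEFAULT_EVENTS_PER_GENERATION):
    """Convenience wrapper: build the transition model and run EM.

    For call data either an initial ``GenotypeEmission`` or a founder allele
    table must be provided; for intensity data pass an ``IntensityEmission``
    (e.g. from ``init_intensity_emission``) and ``data = (theta, rho)``.
    """
    transition = build_transition(map, G, space, events_per_generation)
    if emission is None:
        if isinstance(data, GenotypeCalls) and founder_alleles is not None:
            emission = init_genotype_emission(founder_alleles, space)
        else:
            raise ValueError("an initial emission model is required")
    return em_fit(data, map, transition, emission, tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# Marginal reconstruction, phasing, recombination counting
# ---------------------------------------------------------------------------

def marginal_reconstruction(probs: DiplotypeProbs):
    """Argmax diplotype state per (sample, marker); ties -> lowest index, flagged.

    Returns ``(states, tie_flags)`` with shapes (n, M).
    """
    p = probs.probs
    states = p.argmax(axis=2)
    pmax = p.max(axis=2)
    ties = (np.isclose(p, pmax[..., None], rtol=0, atol=1e-12).sum(axis=2)) > 1
    return states.astype(np.int32), ties


def phase(states: np.ndarray, map: MarkerMap, space: DiplotypeStateSpace,
          samples=None) -> PhasedReconstruction:
    """Phase argmax diplotypes into two haplotype strands per chromosome.

    Dynamic programming over the two possible strand orientations of each
    marker's unordered pair, minimizing the total number of strand switches;
    ancestry-switch breakpoints are placed at the bp midpoint between the
    flanking markers.
    """
    n = states.shape[0]
    samples = samples or [f"S{i:04d}" for i in range(n)]
    pair_arr = np.array(space.pairs)  # (S, 2)
    hap1: dict = {}
    hap2: dict = {}
    bps: dict = {}
    for chrom in map.chromosomes:
        sl = map.chrom_slice(chrom)
        bp_pos = map.bp(chrom)
        st = states[:, sl]
        Mc = st.shape[1]
        h1 = np.empty((n, Mc), dtype=np.int8)
        h2 = np.empty((n, Mc), dtype=np.int8)
        for i in range(n):
            a = pair_arr[st[i], 0]
            b = pair_arr[st[i], 1]
            o1, o2 = _phase_chain(a, b)
            h1[i], h2[i] = o1, o2
            switches = np.flatnonzero((o1[:-1] != o1[1:]) | (o2[:-1] != o2[1:]))
            mid = ((bp_pos[switches] + bp_pos[switches + 1]) / 2.0)
            bps[(samples[i], chrom)] = mid.tolist()
        hap1[chrom] = h1
        hap2[chrom] = h2
    return PhasedReconstruction(list(samples), hap1, hap2, bps)


def _phase_chain(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-switch assignment of unordered pairs (a_j, b_j) to two strands."""
    M = len(a)
    # orientation 0: (a->strand1, b->strand2); orientation 1: swapped
    cost = np.zeros((M, 2))
    back = np.zeros((M, 2), dtype=np.int8)
    for j in range(1, M):
        prev = np.array([[a[j - 1], b[j - 1]], [b[j - 1], a[j - 1]]])
        cur = np.array([[a[j], b[j]], [b[j], a[j]]])
        for o in (0, 1):
            trans = [
                cost[j - 1, po] + (prev[po, 0] != cur[o, 0]) + (prev[po, 1] != cur[o, 1])
                for po in (0, 1)
            ]
            back[j, o] = int(trans[1] < trans[0])
            cost[j, o] = min(trans)
    o = int(cost[-1, 1] < cost[-1, 0])
    orient = np.empty(M, dtype=np.int8)
    orient[-1] = o
    for j in range(M - 1, 0, -1):
        o = back[j, o]
        orient[j - 1] = o
    s1 = np.where(orient == 0, a, b)
    s2 = np.where(orient == 0, b, a)
    return s1.astype(np.int8), s2.astype(np.int8)


def count_recombinations(recon: PhasedReconstruction, map: MarkerMap) -> np.ndarray:
    """Per-sample autosomal ancestry-switch count over both haplotype strands."""
    n = len(recon.samples)
    counts = np.zeros(n, dtype=np.int64)
    for chrom in map.autosomes:
        if chrom not in recon.hap1:
            continue
        for strand in (recon.hap1[chrom], recon.hap2[chrom]):
            counts += (strand[:, :-1] != strand[:, 1:]).sum(axis=1)
    return counts
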