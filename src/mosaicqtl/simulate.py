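"""Synthetic Diversity Outbred (DO) data generator.

Simulates the statistical structure that the reconstruction and mapping
methods assume, without requiring any real array data:

* founder-mosaic genomes from a randomized outbreeding design (default 175
  mating pairs seeded from random founder-pair F1s, with sibling-mating
  avoidance and a no-interference Poisson crossover process on the cM map);
* genotyping-array observations — genotype calls with configurable error and
  state-dependent no-call rates, and two-channel intensities drawn from
  per-state Gaussian clusters in polar coordinates (including "nonconforming"
  markers where off-target variants split the three canonical clusters);
* phenotypes composed of a biallelic QTL term, a polygenic term with
  kinship-structured covariance, and independent Gaussian noise, each
  background component with unit variance.

All generators are driven by an explicit ``numpy.random.Generator`` and are
bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (
    CALL_INDEX,
    DiplotypeStateSpace,
    FounderPanel,
    GenotypeCalls,
    IntensityData,
    MarkerMap,
    expected_genotype,
)

# Approximate mouse autosome lengths: genetic (cM) and physical (Mb).
MOUSE_AUTOSOME_CM = {
    "1": 98.5, "2": 103.9, "3": 82.7, "4": 88.6, "5": 90.2, "6": 79.1,
    "7": 89.1, "8": 76.2, "9": 75.1, "10": 77.9, "11": 88.0, "12": 63.9,
    "13": 67.3, "14": 66.4, "15": 59.0, "16": 57.8, "17": 61.0, "18": 59.4,
    "19": 57.1,
}
MOUSE_AUTOSOME_MB = {
    "1": 195.0, "2": 182.0, "3": 160.0, "4": 157.0, "5": 152.0, "6": 150.0,
    "7": 145.0, "8": 130.0, "9": 124.0, "10": 131.0, "11": 122.0, "12": 120.0,
    "13": 120.0, "14": 125.0, "15": 104.0, "16": 98.0, "17": 95.0, "18": 91.0,
    "19": 61.0,
}


def default_marker_map(n_markers: int = 500, chromosomes=None) -> MarkerMap:
    """Evenly spaced marker map over the mouse autosomes.

    Markers are allocated to chromosomes proportionally to genetic length
    (at least 2 per chromosome) and placed uniformly in cM, with bp assigned
    by linear scaling of the chromosome's physical length.
    """
    if chromosomes is None:
        chromosomes = list(MOUSE_AUTOSOME_CM)
    cm_len = np.array([MOUSE_AUTOSOME_CM[c] for c in chromosomes])
    alloc = np.maximum(2, np.round(n_markers * cm_len / cm_len.sum()).astype(int))
    rows = []
    for chrom, m in zip(chromosomes, alloc):
        L_cm = MOUSE_AUTOSOME_CM[chrom]
        L_bp = MOUSE_AUTOSOME_MB[chrom] * 1e6
        cm = np.linspace(0.0, L_cm, m + 2)[1:-1]
        bp = np.maximum(1, np.round(cm / L_cm * L_bp)).astype(np.int64)
        for k in range(m):
            rows.append((f"M{chrom}_{k:04d}", chrom, bp[k], cm[k]))
    return MarkerMap(pd.DataFrame(rows, columns=["marker", "chr", "bp", "cM"]))


def random_founder_alleles(map: MarkerMap, n_founders: int = 8, rng=None) -> np.ndarray:
    """Random biallelic founder alleles (0/1) per marker, polymorphic at each.

    Alternative-allele counts are drawn uniformly from 1..F-1 so every marker
    segregates in the panel.
    """
    rng = np.random.default_rng(rng)
    M = map.n_markers
    alleles = np.zeros((M, n_founders), dtype=np.int8)
    n_alt = rng.integers(1, n_founders, size=M)
    for j in range(M):
        alleles[j, rng.choice(n_founders, size=n_alt[j], replace=False)] = 1
    return alleles


# ---------------------------------------------------------------------------
# Breeding simulator
# ---------------------------------------------------------------------------

@dataclass
class BreedingConfig:
    """Outbreeding design: ``n_pairs`` mating pairs bred for ``n_generations``.

    ``founding_switch_rate`` (ancestry switches per Morgan per haplotype)
    controls the G1 seeding.  The real population's founding animals carried
    mosaic genomes accumulated through earlier funnel breeding; a positive
    rate seeds G1 haplotypes as random founder mosaics with that switch
    density, which keeps founder representation balanced.  A rate of 0
    seeds G1 as F1s of random distinct founder pairs (every G1 animal
    heterozygous at every locus) — useful for idealized tests.
    """

    n_pairs: int = 175
    n_generations: int = 8
    n_final: int | None = None  # individuals emitted at the last generation
    founding_switch_rate: float = 2.0

    def __post_init__(self):
        if self.n_pairs < 1 or self.n_generations < 1:
            raise ValueError("n_pairs and n_generations must be >= 1")
        if self.founding_switch_rate < 0:
            raise ValueError("founding_switch_rate must be >= 0")


class Haplotype:
    """One chromosome's founder mosaic: segment ends (cM) and founder labels."""

    __slots__ = ("breaks", "labels")

    def __init__(self, breaks: np.ndarray, labels: np.ndarray):
        self.breaks = breaks   # ascending, last entry = chromosome length
        self.labels = labels   # founder index per segment

    def at(self, pos_cm: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.breaks, pos_cm, side="left")
        idx = np.minimum(idx, len(self.labels) - 1)
        return self.labels[idx]

    def n_breakpoints(self) -> int:
        return len(self.labels) - 1


@dataclass
class Individual:
    """Phased founder mosaic across chromosomes, plus pedigree bookkeeping."""

    haplos: dict        # chrom -> (Haplotype, Haplotype)
    parents: tuple = (-1, -1)
    generation: int = 0

    def n_breakpoints(self, chromosomes=None) -> int:
        chroms = chromosomes if chromosomes is not None else self.haplos.keys()
        return sum(
            self.haplos[c][0].n_breakpoints() + self.haplos[c][1].n_breakpoints()
            for c in chroms
        )


def _merge(breaks: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(labels) <= 1:
        return breaks, labels
    keep = np.empty(len(labels), dtype=bool)
    keep[:-1] = labels[:-1] != labels[1:]
    keep[-1] = True
    return breaks[keep], labels[keep]


def _meiosis(pair: tuple[Haplotype, Haplotype], length_cm: float, rng) -> Haplotype:
    """Recombinant gamete: Poisson (no-interference) crossovers on the cM map."""
    n_xo = rng.poisson(length_cm / 100.0)
    start = rng.integers(2)
    if n_xo == 0:
        h = pair[start]
        return Haplotype(h.breaks.copy(), h.labels.copy())
    xo = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    bounds = np.concatenate([[0.0], xo, [length_cm]])
    out_breaks: list[float] = []
    out_labels: list[int] = []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        h = pair[(start + k) % 2]
        i0 = np.searchsorted(h.breaks, lo, side="right")
        i1 = np.searchsorted(h.breaks, hi, side="left")
        i1 = min(i1, len(h.labels) - 1)
        for seg in range(i0, i1 + 1):
            out_breaks.append(min(h.breaks[seg], hi))
            out_labels.append(h.labels[seg])
    breaks = np.asarray(out_breaks)
    labels = np.asarray(out_labels, dtype=np.int8)
    breaks[-1] = length_cm
    breaks, labels = _merge(breaks, labels)
    return Haplotype(breaks, labels)


def _founder_chromosome(f: int, length_cm: float) -> Haplotype:
    return Haplotype(np.array([length_cm]), np.array([f], dtype=np.int8))


def _random_mosaic(F: int, length_cm: float, rate_per_morgan: float, rng) -> Haplotype:
    """Random founder mosaic: Poisson switch points, uniform founder labels."""
    n_sw = rng.poisson(rate_per_morgan * length_cm / 100.0)
    breaks = np.append(np.sort(rng.uniform(0.0, length_cm, size=n_sw)), length_cm)
    labels = rng.integers(0, F, size=n_sw + 1).astype(np.int8)
    breaks, labels = _merge(breaks, labels)
    return Haplotype(breaks, labels)


class Population:
    """A simulated cohort with full ground truth (phased founder mosaics)."""

    def __init__(self, individuals: list[Individual], panel: FounderPanel,
                 map: MarkerMap, generation: int):
        self.individuals = individuals
        self.panel = panel
        self.map = map
        self.generation = generation

    def __len__(self):
        return len(self.individuals)

    @property
    def chrom_lengths_cm(self) -> dict:
        return {c: float(self.map.cM(c)[-1]) for c in self.map.chromosomes}

    # -- marker-level views ------------------------------------------------
    def haplotype_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, M) founder indices for each of the two phased haplotypes."""
        n, M = len(self), self.map.n_markers
        h1 = np.empty((n, M), dtype=np.int8)
        h2 = np.empty((n, M), dtype=np.int8)
        for chrom in self.map.chromosomes:
            sl = self.map.chrom_slice(chrom)
            pos = self.map.cM(chrom)
            for i, ind in enumerate(self.individuals):
                a, b = ind.haplos[chrom]
                h1[i, sl] = a.at(pos)
                h2[i, sl] = b.at(pos)
        return h1, h2

    def state_indices(self, space: DiplotypeStateSpace) -> np.ndarray:
        """(n, M) true diplotype state index per sample per marker."""
        h1, h2 = self.haplotype_labels()
        lo = np.minimum(h1, h2).astype(np.int64)
        hi = np.maximum(h1, h2).astype(np.int64)
        F = space.panel.n_founders
        pair_to_state = np.zeros((F, F), dtype=np.int64)
        for s, (a, b) in enumerate(space.pairs):
            pair_to_state[a, b] = s
        return pair_to_state[lo, hi]

    def dosages(self, space: DiplotypeStateSpace) -> np.ndarray:
        """(n, M, F) true founder allelic dosages (0/1/2)."""
        h1, h2 = self.haplotype_labels()
        F = space.panel.n_founders
        d = np.zeros((len(self), self.map.n_markers, F), dtype=np.float64)
        rows = np.arange(len(self))[:, None]
        cols = np.arange(self.map.n_markers)[None, :]
        np.add.at(d, (rows, cols, h1.astype(np.int64)), 1.0)
        np.add.at(d, (rows, cols, h2.astype(np.int64)), 1.0)
        return d

    def founder_shares(self) -> np.ndarray:
        """(n, F) fraction of each genome (by cM length) inherited from each founder."""
        F = self.panel.n_founders
        shares = np.zeros((len(self), F))
        total = sum(self.chrom_lengths_cm.values())
        for i, ind in enumerate(self.individuals):
            for chrom, (a, b) in ind.haplos.items():
                for h in (a, b):
                    seg_len = np.diff(np.concatenate([[0.0], h.breaks]))
                    np.add.at(shares[i], h.labels.astype(np.int64), seg_len)
        return shares / (2.0 * total)

    def breakpoint_counts(self, autosomes_only: bool = True) -> np.ndarray:
        chroms = self.map.autosomes if autosomes_only else self.map.chromosomes
        return np.array([ind.n_breakpoints(chroms) for ind in self.individuals])


def breed_do(config: BreedingConfig, map: MarkerMap,
             panel: FounderPanel | None = None, rng=None) -> Population:
    """Simulate a randomized outbreeding population on the given marker map.

    Generation 1 is seeded with random founder mosaics approximating the
    funnel-bred founding animals (see ``BreedingConfig.founding_switch_rate``).
    Each later generation forms ``n_pairs`` random mating pairs, avoiding
    full siblings, and each pair contributes offspring so the census size
    stays at ``2 * n_pairs``.
    """
    rng = np.random.default_rng(rng)
    panel = panel or FounderPanel()
    if map.n_markers == 0:
        raise ValueError("empty marker map")
    F = panel.n_founders
    lengths = {c: float(map.cM(c)[-1]) for c in map.chromosomes}
    pop_size = 2 * config.n_pairs

    # G1: mosaic founders (pre-funnel history) or plain F1s when rate is 0
    current: list[Individual] = []
    rate = config.founding_switch_rate
    for i in range(pop_size):
        if rate > 0:
            haplos = {
                c: (_random_mosaic(F, L, rate, rng),
                    _random_mosaic(F, L, rate, rng))
                for c, L in lengths.items()
            }
        else:
            f1, f2 = rng.choice(F, size=2, replace=False)
            haplos = {
                c: (_founder_chromosome(f1, L), _founder_chromosome(f2, L))
                for c, L in lengths.items()
            }
        current.append(Individual(haplos, parents=(-1, -1), generation=1))

    for gen in range(2, config.n_generations + 1):
        pairs = _mate_pairs(current, config.n_pairs, rng)
        is_last = gen == config.n_generations
        n_out = (config.n_final or pop_size) if is_last else pop_size
        nxt: list[Individual] = []
        for k in range(n_out):
            mom_i, dad_i = pairs[k % len(pairs)]
            mom, dad = current[mom_i], current[dad_i]
            haplos = {
                c: (
                    _meiosis(mom.haplos[c], lengths[c], rng),
                    _meiosis(dad.haplos[c], lengths[c], rng),
                )
                for c in lengths
            }
            nxt.append(Individual(haplos, parents=(mom_i, dad_i), generation=gen))
        current = nxt

    return Population(current, panel, map, config.n_generations)


def _mate_pairs(pop: list[Individual], n_pairs: int, rng) -> list[tuple[int, int]]:
    """Random pairing without replacement, re-drawing full-sibling pairs."""
    order = rng.permutation(len(pop))
    pairs = []
    for k in range(n_pairs):
        a, b = order[2 * k], order[2 * k + 1]
        if pop[a].parents == pop[b].parents and pop[a].parents != (-1, -1):
            # swap with a partner from another pair when possible
            for k2 in range(n_pairs):
                c = order[2 * k2]
                if k2 != k and pop[c].parents != pop[a].parents:
                    order[2 * k + 1], order[2 * k2] = order[2 * k2], order[2 * k + 1]
                    b = order[2 * k + 1]
                    break
        pairs.append((int(a), int(b)))
    return pairs


def diplotype_frequencies(states: np.ndarray, space: DiplotypeStateSpace) -> np.ndarray:
    """Frequency of each diplotype state over all (sample, marker) cells."""
    counts = np.bincount(states.ravel(), minlength=space.n_states)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Array observation models
# ---------------------------------------------------------------------------

@dataclass
class ArrayNoiseModel:
    """Noise model for simulated array observations.

    ``call_error`` is the probability mass moved off the expected genotype
    call onto each wrong call; ``no_call_rate`` is the baseline probability
    of an N outcome; ``state_no_call`` optionally overrides the N rate for
    specific diplotype states (two-letter code -> rate), emulating probes
    where one founder's alleles fail to hybridize.  ``theta_sd``/``rho_sd``
    are the per-cluster Gaussian spreads in polar intensity coordinates, and
    ``nonconforming_fraction`` is the share of markers whose intensity
    clusters split beyond the canonical three (off-target variants).
    """

    call_error: float = 0.01
    no_call_rate: float = 0.01
    state_no_call: dict = field(default_factory=dict)
    theta_sd: float = 0.035
    rho_sd: float = 0.08
    nonconforming_fraction: float = 0.15

    def __post_init__(self):
        for p in (self.call_error, self.no_call_rate, self.nonconforming_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for r in self.state_no_call.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("no-call rates must lie in [0, 1]")
        if self.theta_sd < 0 or self.rho_sd < 0:
            raise ValueError("cluster SDs must be non-negative")


def call_distributions(founder_alleles: np.ndarray, space: DiplotypeStateSpace,
                       noise: ArrayNoiseModel) -> np.ndarray:
    """(M, S, 4) multinomial over {A,H,B,N} for each marker and true state."""
    geno = expected_genotype(founder_alleles, space)  # (M, S) in {0,1,2}
    M, S = geno.shape
    ncall = np.full(S, noise.no_call_rate)
    for st, rate in noise.state_no_call.items():
        ncall[space.index(st)] = rate
    P = np.zeros((M, S, 4))
    P[..., 3] = ncall[None, :]
    err = noise.call_error
    for g in range(3):
        mask = geno == g
        others = [c for c in range(3) if c != g]
        P[..., g][mask] = 1.0 - ncall[None, :].repeat(M, 0)[mask] - 2 * err
        for o in others:
            P[..., o][mask] = err
    if P.min() < 0:
        raise ValueError("noise model leaves negative probability for expected call")
    return P


def generate_calls(states: np.ndarray, founder_alleles: np.ndarray,
                   space: DiplotypeStateSpace, noise: ArrayNoiseModel,
                   rng=None, samples=None) -> GenotypeCalls:
    """Draw genotype calls from the per-state multinomial observation model."""
    rng = np.random.default_rng(rng)
    n, M = states.shape
    P = call_distributions(founder_alleles, space, noise)  # (M, S, 4)
    probs = P[np.arange(M)[None, :], states]               # (n, M, 4)
    cum = probs.cumsum(axis=-1)
    u = rng.random((n, M, 1))
    codes = (u > cum[..., :-1]).sum(axis=-1).astype(np.int8)
    samples = samples or [f"S{i:04d}" for i in range(n)]
    return GenotypeCalls(list(samples), codes)


@dataclass
class IntensityClusterModel:
    """Per-marker, per-state polar-coordinate cluster parameters."""

    mu_theta: np.ndarray  # (M, S)
    mu_rho: np.ndarray
    sd_theta: np.ndarray
    sd_rho: np.ndarray

    def __post_init__(self):
        if (self.sd_theta < 0).any() or (self.sd_rho < 0).any():
            raise ValueError("cluster SDs must be non-negative")


#: canonical theta cluster centers for A / H / B genotype classes
_THETA_BY_GENO = np.array([0.12, 0.50, 0.88])


def default_cluster_model(founder_alleles: np.ndarray, space: DiplotypeStateSpace,
                          noise: ArrayNoiseModel, rng=None) -> IntensityClusterModel:
    """Cluster layout implied by founder genotypes, with nonconforming markers.

    Conforming markers collapse the 36 states onto the three canonical
    (A, H, B) cluster centers.  A ``nonconforming_fraction`` of markers gets
    one founder displaced in rho (off-target variant), splitting states that
    carry that founder into extra clusters — up to 6 distinct centers.
    """
    rng = np.random.default_rng(rng)
    geno = expected_genotype(founder_alleles, space)
    M, S = geno.shape
    mu_theta = _THETA_BY_GENO[geno].astype(float)
    mu_rho = np.full((M, S), 1.0)
    n_bad = int(round(noise.nonconforming_fraction * M))
    if n_bad:
        bad = rng.choice(M, size=n_bad, replace=False)
        Ncount = space.N  # (F, S)
        for j in bad:
            f = rng.integers(space.panel.n_founders)
            carry = Ncount[f]  # 0, 1 or 2 copies of the displaced founder
            mu_rho[j] = 1.0 - 0.35 * carry / 2.0 * (carry > 0)
            mu_theta[j] = mu_theta[j] + 0.0  # theta unchanged; rho splits clusters
    sd_t = np.full((M, S), noise.theta_sd)
    sd_r = np.full((M, S), noise.rho_sd)
    return IntensityClusterModel(mu_theta, mu_rho, sd_t, sd_r)


def generate_intensities(states: np.ndarray, clusters: IntensityClusterModel,
                         rng=None, samples=None) -> IntensityData:
    """Draw (X, Y) intensities: polar Gaussian per true state, inverted to x/y."""
    rng = np.random.default_rng(rng)
    n, M = states.shape
    jj = np.arange(M)[None, :]
    theta = clusters.mu_theta[jj, states] + rng.standard_normal((n, M)) * clusters.sd_theta[jj, states]
    rho = clusters.mu_rho[jj, states] + rng.standard_normal((n, M)) * clusters.sd_rho[jj, states]
    theta = np.clip(theta, 0.0, 1.0)
    rho = np.maximum(rho, 0.0)
    ang = theta * (np.pi / 2.0)
    x = rho * np.cos(ang)
    y = rho * np.sin(ang)
    samples = samples or [f"S{i:04d}" for i in range(n)]
    return IntensityData(list(samples), x, y)


# ---------------------------------------------------------------------------
# Phenotype simulator
# ---------------------------------------------------------------------------

@dataclass
class PhenoSimConfig:
    """Phenotype = QTL term + polygenic background + iid error.

    ``maf`` is the number of founder strains (1-4) carrying the causative
    minor allele; ``effect`` is the standardized homozygote effect: +effect
    for minor-allele homozygotes, -effect for major-allele homozygotes, 0
    for heterozygotes.  Polygenic and error variances default to 1 each.
    """

    n: int
    maf: int = 2
    effect: float = 0.5
    polygenic_var: float = 1.0
    error_var: float = 1.0
    qtl_marker: int | None = None  # map row index; None = random autosomal

    def __post_init__(self):
        if not 1 <= self.maf <= 4:
            raise ValueError("maf must be in 1..4 (founder count of the minor allele)")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")


def simulate_phenotype(dosages: np.ndarray, map: MarkerMap, config: PhenoSimConfig,
                       kinship: np.ndarray | None = None, rng=None):
    """Simulate a QTL phenotype on founder dosages.

    Returns ``(y, truth)`` where ``truth`` records the QTL marker index,
    minor-allele founders, per-sample QTL genotype and realized QTL term.
    """
    rng = np.random.default_rng(rng)
    n, M, F = dosages.shape
    if n != config.n:
        raise ValueError("dosage array does not match configured sample size")
    if config.qtl_marker is None:
        auto = np.flatnonzero(np.isin(map.table["chr"].to_numpy(),
                                      np.array(map.autosomes, dtype=object)))
        qtl = int(rng.choice(auto))
    else:
        qtl = int(config.qtl_marker)
        if not 0 <= qtl < M:
            raise ValueError("QTL marker index outside the map")
    minor = rng.choice(F, size=config.maf, replace=False)
    minor_dose = dosages[:, qtl, :][:, minor].sum(axis=1)  # 0..2 minor alleles
    qtl_term = np.where(minor_dose >= 2 - 1e-9, config.effect,
                        np.where(minor_dose <= 1e-9, -config.effect, 0.0))
    if kinship is None:
        polygenic = rng.standard_normal(n) * np.sqrt(config.polygenic_var)
    else:
        K = np.asarray(kinship, float)
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        polygenic = np.sqrt(config.polygenic_var) * (L @ rng.standard_normal(n))
    error = rng.standard_normal(n) * np.sqrt(config.error_var)
    y = qtl_term + polygenic + error
    truth = {
        "qtl_marker": qtl,
        "chrom": map.table.loc[qtl, "chr"],
        "bp": int(map.table.loc[qtl, "bp"]),
        "minor_founders": np.sort(minor),
        "minor_dose": minor_dose,
        "qtl_term": qtl_term,
    }
    return y, truth
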