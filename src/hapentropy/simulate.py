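"""Forward-in-time Wright-Fisher simulator of gradient-recombination model chromosomes.

The model chromosome has L loci (default 500). The recombination
probability between locus j and j+1 falls off exponentially with position,

    r_j = exp(-j / decay),    decay = 25 by default,

so one chromosome end recombines essentially every generation (r_1 ~ 0.96)
while the other effectively never does (r_500 ~ 2.1e-9). Scanning sampled
chromosomes for haplotype diversity therefore probes, within a single
replicate, the whole range from free recombination (high entropy, short
haplotypes) to complete linkage (low entropy, long shared haplotypes).

Reproduction is neutral discrete-generation Wright-Fisher over N diploids:
each offspring draws two parents uniformly with replacement (selfing
allowed); each transmitted gamete starts on a random parental chromosome
and crosses over between locus j and j+1 with probability r_j
independently, so multiple crossovers per gamete are possible; each locus
then mutates (symmetric 0<->1 flip) with probability ``mu`` per generation.
Initial allele frequencies k are drawn once per locus from Uniform(0,1)
and chromosomes seeded i.i.d. Bernoulli(k), so starting inter-locus LD is
~0 and all structure visible at the end was built by drift and linkage.

The full-scale conditions (N=10,000, G=5,000, 100 replicates) are exposed
via :meth:`SimConfig.full_scale`; the package's own test-scale defaults
(N=1,000, G=1,000) keep a replicate in the tens of seconds on one core.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .panel import HaplotypePanel

__all__ = ["SimConfig", "SimResult", "recombination_rate", "init_population",
           "step_generation", "run_replicate", "run_replicate_pair", "run_replicates"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one model-chromosome replicate.

    L : number of loci (evenly spaced; synthetic positions ``spacing_bp`` apart)
    decay : gradient constant of r_j = exp(-j/decay)
    N : diploid population size
    G : generations to evolve
    mu : per-locus per-generation symmetric mutation probability
    n_sample : chromosomes sampled at the end (as n_sample/2 whole diploids)
    seed : RNG seed; the run is fully reproducible from (seed, config)
    """

    L: int = 500
    decay: float = 25.0
    N: int = 1_000
    G: int = 1_000
    mu: float = 2.0e-9
    n_sample: int = 120
    seed: int = 0
    spacing_bp: int = 1_000
    chrom_label: str = "sim1"

    def __post_init__(self) -> None:
        if min(self.L, self.N, self.n_sample) <= 0 or self.G < 0:
            raise ValueError("L, N, n_sample must be positive and G non-negative")
        if self.n_sample > 2 * self.N:
            raise ValueError("cannot sample more chromosomes than the population holds")
        if self.n_sample % 2:
            raise ValueError("n_sample must be even (whole diploids are sampled)")
        if not (0 <= self.mu <= 1):
            raise ValueError("mu must be a probability")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "SimConfig":
        """Full-scale conditions (hours of CPU per replicate)."""
        return cls(L=500, decay=25.0, N=10_000, G=5_000, mu=2.0e-9,
                   n_sample=120, seed=seed)

    def rates(self) -> np.ndarray:
        """r_j for j = 1..L (the last entry is unused: L-1 intervals)."""
        j = np.arange(1, self.L + 1, dtype=float)
        return np.minimum(np.exp(-j / self.decay), 1.0)


@dataclass
class SimResult:
    """Sampled chromosomes of one replicate plus full provenance."""

    panel: HaplotypePanel
    locus_rate: np.ndarray
    init_freq: np.ndarray
    replicate_id: int
    seed_used: int


def recombination_rate(j: int | np.ndarray, decay: float = 25.0) -> float | np.ndarray:
    """Recombination probability at locus index j (1-based), exp(-j/decay) clipped to 1."""
    j_arr = np.asarray(j)
    if np.any(j_arr < 1):
        raise ValueError("locus index must be >= 1")
    r = np.minimum(np.exp(-j_arr / decay), 1.0)
    return float(r) if np.isscalar(j) else r


def init_population(cfg: SimConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw k ~ U(0,1) per locus, then 2N chromosomes i.i.d. Bernoulli(k).

    Returns (population, k) with population shaped (N, 2, L), dtype int8.
    """
    k = rng.random(cfg.L)
    pop = (rng.random((cfg.N, 2, cfg.L)) < k).astype(np.int8)
    return pop, k


def step_generation(pop: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One Wright-Fisher generation: parent draws, recombination, mutation."""
    N, _, L = pop.shape
    n_gam = 2 * N
    parents = rng.integers(0, N, size=n_gam)
    start = rng.integers(0, 2, size=n_gam)
    # crossover between locus j and j+1 with prob r_j; cumulative parity
    # of crossovers selects which parental chromosome each locus comes from
    r = cfg.rates()[: L - 1]
    xo = rng.random((n_gam, L - 1)) < r
    track = np.empty((n_gam, L), dtype=np.int8)
    track[:, 0] = start
    track[:, 1:] = (start[:, None] + np.cumsum(xo, axis=1)) % 2
    gametes = np.take_along_axis(
        pop[parents], track[:, None, :].astype(np.intp), axis=1
    )[:, 0, :]
    _mutate(gametes, cfg.mu, rng)
    return gametes.reshape(N, 2, L)


def _mutate(gametes: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    """Symmetric 0<->1 flips in place, sparse path for tiny mu."""
    if mu == 0:
        return
    n_cells = gametes.size
    if mu < 1e-4:  # expected flips far below the cost of a dense draw
        n_mut = rng.binomial(n_cells, mu)
        if n_mut:
            idx = rng.choice(n_cells, size=n_mut, replace=False)
            flat = gametes.reshape(-1)
            flat[idx] ^= 1
    else:
        flips = rng.random(gametes.shape) < mu
        gametes ^= flips


def run_replicate(cfg: SimConfig, replicate_id: int = 0) -> SimResult:
    """Evolve one population for G generations and sample whole diploids."""
    rng = np.random.default_rng(cfg.seed)
    pop, k = init_population(cfg, rng)
    for _ in range(cfg.G):
        pop = step_generation(pop, cfg, rng)
    return _sample_result(pop, cfg, rng, k, replicate_id=replicate_id)


def run_replicate_pair(cfg: SimConfig, extra_generations: int) -> tuple[SimResult, SimResult]:
    """Sample the same lineage at two time points: after G and G + extra generations.

    The second sample has experienced additional drift; where recombination
    is too weak to re-randomize haplotypes the extra drift shifts haplotype
    frequencies persistently, so the entropy difference between the two
    samples concentrates at the linked end of the gradient.
    """
    rng = np.random.default_rng(cfg.seed)
    pop, k = init_population(cfg, rng)
    for _ in range(cfg.G):
        pop = step_generation(pop, cfg, rng)
    first = _sample_result(pop, cfg, rng, k, replicate_id=0)
    for _ in range(extra_generations):
        pop = step_generation(pop, cfg, rng)
    second = _sample_result(pop, cfg, rng, k, replicate_id=1)
    return first, second


def _sample_result(pop, cfg: SimConfig, rng, k, replicate_id: int) -> SimResult:
    chosen = rng.choice(cfg.N, size=cfg.n_sample // 2, replace=False)
    sample = pop[np.sort(chosen)].reshape(cfg.n_sample, cfg.L)
    pos = (np.arange(cfg.L) + 1) * cfg.spacing_bp
    panel = HaplotypePanel(
        chrom=np.full(cfg.L, cfg.chrom_label, dtype=object),
        pos=pos,
        snp_id=np.array([f"locus{j}" for j in range(1, cfg.L + 1)], dtype=object),
        alleles=sample.T.copy(),
    )
    return SimResult(panel=panel, locus_rate=cfg.rates(), init_freq=k,
                     replicate_id=replicate_id, seed_used=cfg.seed)


def run_replicates(cfg: SimConfig, reps: int) -> list[SimResult]:
    """Independent replicates with per-replicate seeds derived from cfg.seed."""
    seeds = np.random.SeedSequence(cfg.seed).generate_state(reps) % (2**31)
    return [
        run_replicate(replace(cfg, seed=int(s)), replicate_id=i)
        for i, s in enumerate(seeds)
    ]
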