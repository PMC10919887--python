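"""Forward-time Wright-Fisher simulation of an emergent ZW system.

A population of N diploids evolves with nonoverlapping generations.  Sex is
not a label but a consequence of genotype at the focal gene: an individual
with at least one functional copy is female (W/Z or, transiently, W/W), an
individual with two loss-of-function copies is male (Z/Z).  Each offspring
draws a mother uniformly from the females and a father uniformly from the
males (with replacement) and receives one gamete from each.

Meiosis applies, in order:

1. a single crossover with probability ``min(1, L * r)`` where
   ``r = r0 * max(0, 1 - c * d)`` and ``d`` is the raw count of sites at
   which the parent's two haplotypes differ (divergence suppresses
   recombination); otherwise one parental haplotype is copied, each with
   probability 1/2;
2. a Poisson(``mu * L``) number of point mutations at uniform positions,
   each to a uniform choice among the three alternatives to the current
   base (finite sites: recurrent and back mutation are possible).

Two engines produce identically distributed results: the naive
per-individual engine in this module (transparent, used for validation)
and the optimized genotype-count engine in :mod:`zwturnover._countsim`
(default; required for 100,000-generation batches).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .locus import GeneModel, is_functional

COMPLETED = "completed"
EXTINCT = "extinct_single_sex"


# --------------------------------------------------------------------- #
# parameters and domain types


@dataclass
class SimParams:
    """Wright-Fisher run configuration.

    ``mu`` and ``r0`` are per site per generation/meiosis; ``c`` is the
    recombination-divergence coefficient (fractional reduction of the
    recombination rate per pairwise difference, clamped at zero);
    ``pop_chromosomes`` is 2N.
    """

    gene_model: GeneModel
    mu: float = 1e-8
    r0: float = 1e-8
    c: float = 0.03
    pop_chromosomes: int = 100
    generations: int = 100_000
    seed: int = 0
    record_every: int | None = None

    def validate(self) -> None:
        if self.pop_chromosomes < 4 or self.pop_chromosomes % 2:
            raise ValueError("pop_chromosomes must be even and >= 4")
        if self.mu < 0 or self.r0 < 0 or self.c < 0:
            raise ValueError("mu, r0 and c must be non-negative")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.record_every is not None and self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    @property
    def n_individuals(self) -> int:
        return self.pop_chromosomes // 2


@dataclass(frozen=True)
class Haplotype:
    """A chromosome copy as differences from the reference sequence."""

    diffs: tuple[tuple[int, str], ...]  # sorted (position, base) pairs
    functional: bool

    @classmethod
    def from_diffs(cls, diffs: Mapping[int, str], gene_model: GeneModel) -> "Haplotype":
        return cls(tuple(sorted(diffs.items())), is_functional(diffs, gene_model))

    def diffs_dict(self) -> dict[int, str]:
        return dict(self.diffs)

    def sequence(self, gene_model: GeneModel) -> str:
        seq = list(gene_model.reference_sequence)
        for p, b in self.diffs:
            seq[p] = b
        return "".join(seq)


@dataclass(frozen=True)
class Individual:
    haplotypes: tuple[Haplotype, Haplotype]

    @property
    def is_female(self) -> bool:
        return self.haplotypes[0].functional or self.haplotypes[1].functional

    @property
    def sex(self) -> str:
        return "F" if self.is_female else "M"


@dataclass
class PopulationState:
    generation: int
    individuals: list[Individual]

    def sex_counts(self) -> tuple[int, int]:
        f = sum(1 for ind in self.individuals if ind.is_female)
        return f, len(self.individuals) - f

    def haplotype_counts(self) -> list[tuple[Haplotype, int]]:
        c: Counter[Haplotype] = Counter()
        for ind in self.individuals:
            c.update(ind.haplotypes)
        return list(c.items())


@dataclass
class DiversityStats:
    """Average pairwise difference counts per segment (not per site)."""

    pi_all: float
    pi_w: float
    pi_z: float
    dxy: float
    fst: float


@dataclass
class ReplicateResult:
    seed: int
    termination_status: str
    generations_run: int
    census: "CensusResult"
    diversity: DiversityStats
    params: SimParams
    # final collapsed haplotype inventory: (diffs, functional, count)
    haplotypes: list[tuple[dict[int, str], bool, int]] = field(default_factory=list)
    trajectory: list[tuple[int, int, int, int]] | None = None


# --------------------------------------------------------------------- #
# primitives


def hap_distance(d1: Mapping[int, str], d2: Mapping[int, str]) -> int:
    """Number of sites at which two haplotypes carry different bases."""
    n = 0
    for p, b in d1.items():
        if d2.get(p) != b:
            n += 1
    for p in d2:
        if p not in d1:
            n += 1
    return n


def effective_recombination_rate(r0: float, c: float, d: int) -> float:
    """Per-site recombination rate ``r0 * max(0, 1 - c*d)``.

    Undiverged homologs (d = 0) recombine at the baseline rate; each
    pairwise difference removes a fraction ``c`` of it, clamped at zero.
    """
    if d < 0:
        raise ValueError("pairwise difference count d must be >= 0")
    return r0 * max(0.0, 1.0 - c * d)


def initialize_population(params: SimParams) -> PopulationState:
    """Founding population: ceil(N/2) W/Z females, the rest Z/Z males.

    Every Z haplotype carries exactly the founding splice-donor mutation;
    every W haplotype is the reference.
    """
    params.validate()
    gm = params.gene_model
    w = Haplotype.from_diffs({}, gm)
    z = Haplotype.from_diffs({gm.initial_sd_site: gm.initial_sd_alt_base}, gm)
    if not w.functional or z.functional:
        raise ValueError("gene model's founding SD mutation is not loss-of-function")
    n = params.n_individuals
    n_f = (n + 1) // 2
    inds = [Individual((w, z))] * n_f + [Individual((z, z))] * (n - n_f)
    return PopulationState(0, inds)


def meiosis(parent: Individual, params: SimParams, rng: np.random.Generator) -> Haplotype:
    """Produce one gamete from a parent (crossover, then mutation)."""
    gm = params.gene_model
    L = gm.total_length
    h1, h2 = parent.haplotypes
    d1, d2 = h1.diffs_dict(), h2.diffs_dict()
    d = hap_distance(d1, d2)
    p_co = min(1.0, L * effective_recombination_rate(params.r0, params.c, d))
    if p_co > 0.0 and rng.random() < p_co:
        if rng.random() < 0.5:
            d1, d2 = d2, d1
        bp = int(rng.integers(1, L))
        diffs = {p: b for p, b in d1.items() if p < bp}
        diffs.update({p: b for p, b in d2.items() if p >= bp})
    else:
        diffs = dict(d1 if rng.random() < 0.5 else d2)
    n_mut = int(rng.poisson(params.mu * L)) if params.mu > 0 else 0
    for _ in range(n_mut):
        pos = int(rng.integers(L))
        cur = diffs.get(pos, gm.reference_sequence[pos])
        alts = [b for b in "ACGT" if b != cur]
        new = alts[int(rng.integers(3))]
        if new == gm.reference_sequence[pos]:
            diffs.pop(pos, None)  # back mutation
        else:
            diffs[pos] = new
    return Haplotype.from_diffs(diffs, gm)


def step_generation(
    state: PopulationState, params: SimParams, rng: np.random.Generator
) -> PopulationState:
    """One Wright-Fisher generation (requires both sexes present)."""
    females = [ind for ind in state.individuals if ind.is_female]
    males = [ind for ind in state.individuals if not ind.is_female]
    if not females or not males:
        raise ValueError("cannot reproduce: population is single-sex")
    n = len(state.individuals)
    offspring = []
    for _ in range(n):
        mother = females[int(rng.integers(len(females)))]
        father = males[int(rng.integers(len(males)))]
        offspring.append(Individual((meiosis(mother, params, rng),
                                     meiosis(father, params, rng))))
    return PopulationState(state.generation + 1, offspring)


# --------------------------------------------------------------------- #
# replicate drivers


def run_replicate(params: SimParams, engine: str = "counts") -> ReplicateResult:
    """Run one replicate to completion (or single-sex extinction).

    ``engine="counts"`` (default) uses the optimized genotype-count
    representation; ``engine="naive"`` iterates explicit individuals.
    The two agree in distribution, not draw-for-draw.
    """
    params.validate()
    if engine == "counts":
        from ._countsim import run_counts_replicate

        return run_counts_replicate(params)
    if engine != "naive":
        raise ValueError(f"unknown engine {engine!r}")

    from .census import census_from_counts
    from .stats import diversity_from_counts

    rng = np.random.default_rng(params.seed)
    state = initialize_population(params)
    status = COMPLETED
    trajectory = [] if params.record_every else None
    for g in range(params.generations):
        f, m = state.sex_counts()
        if f == 0 or m == 0:
            status = EXTINCT
            break
        state = step_generation(state, params, rng)
        if trajectory is not None and state.generation % params.record_every == 0:
            f2, m2 = state.sex_counts()
            hap_n = len(state.haplotype_counts())
            trajectory.append((state.generation, f2, m2, hap_n))
    counts = [(h.diffs_dict(), h.functional, c) for h, c in state.haplotype_counts()]
    return ReplicateResult(
        seed=params.seed,
        termination_status=status,
        generations_run=state.generation,
        census=census_from_counts(counts, params.gene_model),
        diversity=diversity_from_counts(counts),
        params=params,
        haplotypes=counts,
        trajectory=trajectory,
    )


@dataclass
class BatchResult:
    params: SimParams
    base_seed: int
    replicates: list[ReplicateResult]
    table1_row: dict

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)


def run_batch(
    params: SimParams,
    n_replicates: int,
    base_seed: int,
    engine: str = "counts",
) -> BatchResult:
    """Run ``n_replicates`` with seeds ``base_seed + index`` and aggregate.

    Returns per-replicate results plus the batch summary row
    (turnover percentage, fixed/nonfixed histograms).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .census import aggregate_table1

    results = []
    for i in range(n_replicates):
        rep = replace(params, seed=base_seed + i)
        results.append(run_replicate(rep, engine=engine))
    return BatchResult(params, base_seed, results, aggregate_table1(results))


# --------------------------------------------------------------------- #
# validation probe


def run_autosomal_probe(
    pop_chromosomes: int,
    init_count: int,
    max_generations: int,
    seed: int,
    gene_model: GeneModel,
) -> str:
    """Neutral-drift sanity probe on autosomal-equivalent bookkeeping.

    Places a neutral (intronic, non-splice) marker on ``init_count`` of the
    ``pop_chromosomes`` chromosomes and reproduces with both parents drawn
    uniformly from the whole population (no sex structure), mu = r0 = 0,
    using the same meiosis machinery as the main model.  Returns
    ``"fixed"``, ``"lost"`` or ``"segregating"``; a new marker at initial
    frequency p should fix with probability p.
    """
    params = SimParams(
        gene_model=gene_model, mu=0.0, r0=0.0, pop_chromosomes=pop_chromosomes,
        generations=max_generations, seed=seed,
    )
    params.validate()
    gm = gene_model
    splice = gm.splice_positions
    marker_pos = next(
        p for s, e in gm.introns for p in range(s, e) if p not in splice
    )
    ref_base = gm.reference_sequence[marker_pos]
    alt = next(b for b in "ACGT" if b != ref_base and not gm.is_lof(marker_pos, b))
    marked = Haplotype.from_diffs({marker_pos: alt}, gm)
    plain = Haplotype.from_diffs({}, gm)

    rng = np.random.default_rng(seed)
    n = pop_chromosomes // 2
    haps = [marked] * init_count + [plain] * (pop_chromosomes - init_count)
    inds = [Individual((haps[2 * i], haps[2 * i + 1])) for i in range(n)]
    for _ in range(max_generations):
        count = sum(h.diffs != () for ind in inds for h in ind.haplotypes)
        if count == 0:
            return "lost"
        if count == pop_chromosomes:
            return "fixed"
        new = []
        for _ in range(n):
            pa = inds[int(rng.integers(n))]
            pb = inds[int(rng.integers(n))]
            new.append(Individual((meiosis(pa, params, rng), meiosis(pb, params, rng))))
        inds = new
    return "segregating"
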