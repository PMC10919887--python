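"""Optimized genotype-count Wright-Fisher engine.

Because offspring are drawn independently given the current population,
the population state is fully summarized by the multiset of diploid
genotypes (unordered pairs of haplotype ids).  Each generation:

* the maternal gamete distribution is a mixture over female genotypes
  (crossover with probability ``min(1, L*r)``, else either haplotype with
  probability 1/2); likewise the paternal distribution over males;
* N maternal and N paternal gametes are drawn count-wise (rare crossover
  and mutation products are materialized individually);
* gametes are paired uniformly at random (sequential multivariate
  hypergeometric), giving the offspring genotype counts.

This is distributionally exact with respect to the naive per-individual
engine; cost per generation is O(distinct haplotypes^2), independent of N.

Fast path: whenever exactly two haplotypes segregate -- one functional
(W), one not (Z) -- with genotypes {W/Z females, Z/Z males}, consecutive
generations are iid: every offspring is female with probability 1/2
independently, and the gamete distribution does not depend on the current
female count.  The engine therefore jumps straight to the next generation
containing an event (a mutation anywhere, or, when d(W,Z) >= 2, a maternal
crossover, which for d = 1 cannot create a new haplotype), drawing the
female count at that generation from a Binomial(N, 1/2) conditioned on
both sexes being present, and accounting for single-sex extinction in the
skipped block exactly (geometric tail); the per-generation single-sex
probability is 2^(1-N), negligible beyond toy population sizes.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.stats import binom as _binom
from scipy.stats import poisson as _poisson

from .locus import GeneModel
from .simulate import (
    COMPLETED,
    EXTINCT,
    ReplicateResult,
    SimParams,
    effective_recombination_rate,
    hap_distance,
)

_ALTS = {b: tuple(x for x in "ACGT" if x != b) for b in "ACGT"}


class HaplotypeRegistry:
    """Interns haplotypes (diff dicts) and caches pairwise distances."""

    def __init__(self, gene_model: GeneModel):
        self.gm = gene_model
        self.diffs: list[dict[int, str]] = []
        self.functional: list[bool] = []
        self.lof: list[frozenset[int]] = []
        self._key2id: dict[tuple, int] = {}
        self._dist: dict[tuple[int, int], int] = {}

    def intern(self, diffs: dict[int, str]) -> int:
        key = tuple(sorted(diffs.items()))
        hid = self._key2id.get(key)
        if hid is None:
            hid = len(self.diffs)
            self._key2id[key] = hid
            self.diffs.append(dict(diffs))
            lof = frozenset(self.gm.lof_positions(diffs))
            self.lof.append(lof)
            self.functional.append(not lof)
        return hid

    def dist(self, i: int, j: int) -> int:
        if i == j:
            return 0
        key = (i, j) if i < j else (j, i)
        d = self._dist.get(key)
        if d is None:
            d = hap_distance(self.diffs[i], self.diffs[j])
            self._dist[key] = d
        return d

    def recombine(self, i: int, j: int, bp: int) -> int:
        """Left of ``bp`` from haplotype i, right from haplotype j."""
        nd = {p: b for p, b in self.diffs[i].items() if p < bp}
        nd.update((p, b) for p, b in self.diffs[j].items() if p >= bp)
        return self.intern(nd)

    def mutate(self, i: int, pos: int, rng: np.random.Generator) -> int:
        ref = self.gm.reference_sequence[pos]
        diffs = self.diffs[i]
        cur = diffs.get(pos, ref)
        new = _ALTS[cur][int(rng.integers(3))]
        nd = dict(diffs)
        if new == ref:
            del nd[pos]  # back mutation restores the reference base
        else:
            nd[pos] = new
        return self.intern(nd)


# --------------------------------------------------------------------- #
# conditioned samplers (used at fast-path event generations)


def _poisson_ge1(lam: float, rng: np.random.Generator) -> int:
    u = rng.uniform(np.exp(-lam), 1.0)
    return max(1, int(_poisson.ppf(u, lam)))


def _binom_ge1(n: int, p: float, rng: np.random.Generator) -> int:
    u = rng.uniform(_binom.cdf(0, n, p), 1.0)
    return max(1, int(_binom.ppf(u, n, p)))


def _both_sex_female_count(n: int, rng: np.random.Generator) -> int:
    """Binomial(n, 1/2) conditioned on 0 < F < n (both sexes present)."""
    while True:
        f = int(rng.binomial(n, 0.5))
        if 0 < f < n:
            return f


# --------------------------------------------------------------------- #
# one generation

Counts = dict[tuple[int, int], int]


def _split_sexes(counts: Counts, reg: HaplotypeRegistry):
    females, males = [], []
    n_f = n_m = 0
    for g, c in counts.items():
        if reg.functional[g[0]] or reg.functional[g[1]]:
            females.append((g, c))
            n_f += c
        else:
            males.append((g, c))
            n_m += c
    return females, n_f, males, n_m


def _draw_gametes(
    genos, total, n_gametes, params: SimParams, reg, rng, force_n_co=None
) -> Counter:
    """Sample the side's gamete counts (crossover products materialized)."""
    L = params.gene_model.total_length
    p_hap: dict[int, float] = {}
    co_w: list[float] = []
    co_g: list[tuple[int, int]] = []
    p_co = 0.0
    for (a, b), c in genos:
        w = c / total
        if a == b:
            p_hap[a] = p_hap.get(a, 0.0) + w
            continue
        r = effective_recombination_rate(params.r0, params.c, reg.dist(a, b))
        pr = min(1.0, L * r)
        if pr > 0.0:
            p_co += w * pr
            co_w.append(w * pr)
            co_g.append((a, b))
        half = w * (1.0 - pr) / 2.0
        p_hap[a] = p_hap.get(a, 0.0) + half
        p_hap[b] = p_hap.get(b, 0.0) + half
    if force_n_co is not None:
        n_co = force_n_co
    else:
        n_co = int(rng.binomial(n_gametes, p_co)) if p_co > 0.0 else 0
    out: Counter = Counter()
    for _ in range(n_co):
        u = rng.random() * p_co
        acc = 0.0
        a, b = co_g[-1]
        for wgt, g in zip(co_w, co_g):
            acc += wgt
            if u < acc:
                a, b = g
                break
        if rng.random() < 0.5:
            a, b = b, a
        bp = int(rng.integers(1, L))
        out[reg.recombine(a, b, bp)] += 1
    rem = n_gametes - n_co
    if rem > 0:
        ids = list(p_hap)
        probs = np.array([p_hap[h] for h in ids], dtype=float)
        probs /= probs.sum()
        for h, c in zip(ids, rng.multinomial(rem, probs)):
            if c:
                out[h] += int(c)
    return out


def _mutate_pool(pool: Counter, n: int, reg, rng) -> None:
    """Apply one point mutation to a uniformly chosen gamete of the pool."""
    k = int(rng.integers(n))
    acc = 0
    target = None
    for h, c in pool.items():
        acc += c
        if k < acc:
            target = h
            break
    pool[target] -= 1
    if pool[target] == 0:
        del pool[target]
    pos = int(rng.integers(reg.gm.total_length))
    pool[reg.mutate(target, pos, rng)] += 1


def _pair(mat: Counter, pat: Counter, rng) -> Counts:
    """Uniform random pairing of the two gamete pools."""
    pat_ids = list(pat)
    pat_cnt = np.array([pat[h] for h in pat_ids], dtype=np.int64)
    off: Counts = {}
    for h, m in mat.items():
        take = rng.multivariate_hypergeometric(pat_cnt, m)
        pat_cnt -= take
        for pid, t in zip(pat_ids, take):
            if t:
                key = (h, pid) if h <= pid else (pid, h)
                off[key] = off.get(key, 0) + int(t)
    return off


def slow_step(
    counts: Counts,
    params: SimParams,
    reg: HaplotypeRegistry,
    rng: np.random.Generator,
    force_n_mut: int | None = None,
    force_n_co_mat: int | None = None,
) -> Counts:
    females, n_f, males, n_m = _split_sexes(counts, reg)
    if n_f == 0 or n_m == 0:
        raise ValueError("cannot reproduce: population is single-sex")
    n = params.n_individuals
    mat = _draw_gametes(females, n_f, n, params, reg, rng, force_n_co_mat)
    pat = _draw_gametes(males, n_m, n, params, reg, rng)
    lam = params.pop_chromosomes * params.mu * params.gene_model.total_length
    if force_n_mut is not None:
        n_mut = force_n_mut
    else:
        n_mut = int(rng.poisson(lam)) if lam > 0 else 0
    for _ in range(n_mut):
        if rng.random() < 0.5:
            _mutate_pool(mat, n, reg, rng)
        else:
            _mutate_pool(pat, n, reg, rng)
    return _pair(mat, pat, rng)


# --------------------------------------------------------------------- #
# fast path


def _detect_fast(counts: Counts, reg: HaplotypeRegistry):
    """Return (w, z) if the state is {W/Z females, Z/Z males}, else None."""
    if len(counts) != 2:
        return None
    (g1, _), (g2, _) = counts.items()
    hom = het = None
    for g in (g1, g2):
        if g[0] == g[1]:
            hom = g
        else:
            het = g
    if hom is None or het is None:
        return None
    z = hom[0]
    if reg.functional[z]:
        return None
    if het[0] == z:
        w = het[1]
    elif het[1] == z:
        w = het[0]
    else:
        return None
    if not reg.functional[w]:
        return None
    return (w, z)


def _block_extinction(k: int, n: int, rng) -> tuple[bool, int]:
    """Single-sex extinction within k iid event-free generations.

    Returns (extinct, generation offset in 1..k).  Per-generation
    probability of a single-sex offspring cohort is 2 * 0.5**n.
    """
    if k <= 0:
        return False, 0
    e = 0.5 ** (n - 1)
    if e <= 0.0:
        return False, 0
    log1me = np.log1p(-e)
    p_block = -np.expm1(k * log1me)
    if rng.random() >= p_block:
        return False, 0
    u = rng.random()
    t = int(np.ceil(np.log1p(-u * p_block) / log1me))
    return True, min(max(t, 1), k)


def _single_sex_state(w: int, z: int, n: int, rng) -> Counts:
    key = (w, z) if w <= z else (z, w)
    return {(z, z): n} if rng.random() < 0.5 else {key: n}


# --------------------------------------------------------------------- #
# replicate driver


def run_counts_replicate(params: SimParams) -> ReplicateResult:
    from .census import census_from_counts
    from .stats import diversity_from_counts

    params.validate()
    gm = params.gene_model
    L = gm.total_length
    n = params.n_individuals
    rng = np.random.default_rng(params.seed)
    reg = HaplotypeRegistry(gm)
    w0 = reg.intern({})
    z0 = reg.intern({gm.initial_sd_site: gm.initial_sd_alt_base})
    if not reg.functional[w0] or reg.functional[z0]:
        raise ValueError("gene model's founding SD mutation is not loss-of-function")
    n_f0 = (n + 1) // 2
    key_wz = (w0, z0) if w0 <= z0 else (z0, w0)
    counts: Counts = {key_wz: n_f0}
    if n - n_f0:
        counts[(z0, z0)] = n - n_f0

    lam_mut = params.pop_chromosomes * params.mu * L
    a_mut = -np.expm1(-lam_mut)  # P(>=1 mutation in a generation)
    gens = params.generations
    record = params.record_every
    trajectory: list[tuple[int, int, int, int]] | None = [] if record else None
    status = COMPLETED
    gen = 0

    # trajectory recording forces per-generation stepping (no jumps)
    while gen < gens:
        females, n_f, males, n_m = _split_sexes(counts, reg)
        if n_f == 0 or n_m == 0:
            status = EXTINCT
            break
        fast = None if record else _detect_fast(counts, reg)
        if fast is None:
            counts = slow_step(counts, params, reg, rng)
            gen += 1
            if trajectory is not None and gen % record == 0:
                _, f2, _, m2 = _split_sexes(counts, reg)
                trajectory.append((gen, f2, m2, len(counts)))
            continue

        w, z = fast
        d = reg.dist(w, z)
        p_r = 0.0
        if d >= 2 and params.r0 > 0.0:
            p_r = min(1.0, L * effective_recombination_rate(params.r0, params.c, d))
        b_co = -np.expm1(n * np.log1p(-p_r)) if p_r > 0.0 else 0.0
        q = 1.0 - (1.0 - a_mut) * (1.0 - b_co)
        remaining = gens - gen
        t_event = int(rng.geometric(q)) if q > 0.0 else remaining + 1
        if t_event > remaining:
            extinct, t = _block_extinction(remaining, n, rng)
            if extinct:
                gen += t
                counts = _single_sex_state(w, z, n, rng)
                if gen < gens:
                    status = EXTINCT
                break
            gen = gens
            f = _both_sex_female_count(n, rng)
            counts = {((w, z) if w <= z else (z, w)): f, (z, z): n - f}
            break
        extinct, t = _block_extinction(t_event - 1, n, rng)
        if extinct:
            gen += t
            counts = _single_sex_state(w, z, n, rng)
            status = EXTINCT
            break
        gen += t_event - 1
        f = _both_sex_female_count(n, rng)
        counts = {((w, z) if w <= z else (z, w)): f, (z, z): n - f}
        # decompose the conditioned event: mutation (A) and/or crossover (B)
        if b_co > 0.0:
            u = rng.random() * q
            p_both = a_mut * b_co
            p_a_only = a_mut * (1.0 - b_co)
            if u < p_both:
                has_a, has_b = True, True
            elif u < p_both + p_a_only:
                has_a, has_b = True, False
            else:
                has_a, has_b = False, True
            n_mut = _poisson_ge1(lam_mut, rng) if has_a else 0
            n_co = _binom_ge1(n, p_r, rng) if has_b else 0
        else:
            n_mut = _poisson_ge1(lam_mut, rng)
            n_co = None  # d <= 1: crossovers are no-ops, sample freely
        counts = slow_step(
            counts, params, reg, rng, force_n_mut=n_mut, force_n_co_mat=n_co
        )
        gen += 1

    hap_counter: Counter = Counter()
    for (h1, h2), c in counts.items():
        hap_counter[h1] += c
        hap_counter[h2] += c
    items = [
        (dict(reg.diffs[h]), reg.functional[h], c) for h, c in hap_counter.items()
    ]
    return ReplicateResult(
        seed=params.seed,
        termination_status=status,
        generations_run=gen,
        census=census_from_counts(items, gm),
        diversity=diversity_from_counts(items),
        params=params,
        haplotypes=items,
        trajectory=trajectory,
    )
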