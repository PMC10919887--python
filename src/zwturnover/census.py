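"""End-state inventory of sex-determining mutations and turnover detection.

A chromosome is W-class when its haplotype is fully functional and Z-class
when it carries at least one loss-of-function (LOF) change.  The census
collects the LOF positions segregating on Z-class chromosomes and splits
them into *fixed* (carried by every Z-class haplotype) and *nonfixed*
(carried by some but not all).  Two different derived bases at one
position count as a single sex-determining position.

A turnover has occurred when the final state carries exactly one fixed
LOF position, that position differs from the founding site, and no
nonfixed LOF positions remain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .locus import GeneModel

# (diffs, functional, count) triples: the collapsed haplotype inventory
HapCounts = Sequence[tuple[Mapping[int, str], bool, int]]


@dataclass
class CensusResult:
    w_class_count: int
    z_class_count: int
    fixed_lof: tuple[int, ...]
    nonfixed_lof: dict[int, float]  # position -> frequency among Z-class
    turnover: bool
    initial_site: int


def census_from_counts(items: HapCounts, gene_model: GeneModel) -> CensusResult:
    """Census from collapsed (diffs, functional, count) haplotype triples."""
    w_count = sum(c for _, func, c in items if func)
    z_items = [(d, c) for d, func, c in items if not func]
    z_count = sum(c for _, c in z_items)
    initial = gene_model.initial_sd_site

    if z_count == 0:
        return CensusResult(w_count, 0, (), {}, False, initial)

    lof_sets = [(frozenset(gene_model.lof_positions(d)), c) for d, c in z_items]
    fixed = frozenset.intersection(*(s for s, _ in lof_sets))
    union = frozenset.union(*(s for s, _ in lof_sets))
    nonfixed = {}
    for p in sorted(union - fixed):
        nonfixed[p] = sum(c for s, c in lof_sets if p in s) / z_count
    result = CensusResult(
        w_class_count=w_count,
        z_class_count=z_count,
        fixed_lof=tuple(sorted(fixed)),
        nonfixed_lof=nonfixed,
        turnover=False,
        initial_site=initial,
    )
    result.turnover = detect_turnover(result, initial)
    return result


def census(population, gene_model: GeneModel) -> CensusResult:
    """Census a :class:`~zwturnover.simulate.PopulationState`."""
    items = [
        (h.diffs_dict(), h.functional, c) for h, c in population.haplotype_counts()
    ]
    return census_from_counts(items, gene_model)


def detect_turnover(census_result: CensusResult, initial_site: int) -> bool:
    """True iff exactly one fixed LOF position, at a new site, and no nonfixed."""
    return (
        len(census_result.fixed_lof) == 1
        and census_result.fixed_lof[0] != initial_site
        and not census_result.nonfixed_lof
    )


def aggregate_table1(results: Iterable) -> dict:
    """Aggregate a batch of replicates into one summary-table row.

    Returns the turnover percentage (TS), histograms of replicates by the
    number of fixed LOF positions (bins 0,1,2,3,4+) and by the number of
    nonfixed LOF positions (bins 0..4,5+), and the >=2 tallies.  Only
    completed replicates enter the histograms.
    """
    results = list(results)
    if not results:
        raise ValueError("empty batch")
    completed = [r for r in results if r.termination_status == "completed"]
    if not completed:
        raise ValueError("no completed replicates in batch")
    n = len(completed)
    fixed_hist = [0] * 5
    nonfixed_hist = [0] * 6
    n_turn = 0
    for r in completed:
        c = r.census
        n_turn += bool(c.turnover)
        fixed_hist[min(len(c.fixed_lof), 4)] += 1
        nonfixed_hist[min(len(c.nonfixed_lof), 5)] += 1
    return {
        "n_replicates": n,
        "n_extinct": len(results) - n,
        "n_turnover": n_turn,
        "ts_percent": 100.0 * n_turn / n,
        "fixed_hist": fixed_hist,
        "nonfixed_hist": nonfixed_hist,
        "n_fixed_ge2": sum(fixed_hist[2:]),
        "n_nonfixed_ge2": sum(nonfixed_hist[2:]),
    }
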