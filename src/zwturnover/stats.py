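"""Diversity and association statistics.

Diversity is reported as the average number of pairwise nucleotide
differences per segment (a count, not a per-site rate): pi within a group
of haplotypes, d_xy between the W-class and Z-class groups, and
Fst = 1 - mean(pi_w, pi_z) / d_xy.  Quantities that are undefined for a
given input (a group of fewer than two haplotypes, d_xy = 0) are returned
as NaN rather than raised.

The association statistics reproduce the small confirmatory tests used
alongside the simulation: a genotypic chi-square of sex against genotype
class at one variant (default: heterozygous vs homozygous, 1 df, no
continuity correction), a ZW/XY heterogamety pattern classifier, a 1:1
sex-ratio chi-square, windowed nucleotide diversity from allele
frequencies, and the male:female read-depth log2 ratio with a 0.1
pseudocount.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from .simulate import DiversityStats, Haplotype, hap_distance

ZW_LIKE = "ZW_like"
XY_LIKE = "XY_like"
NO_PATTERN = "none"


def _diffs_of(h) -> Mapping[int, str]:
    if isinstance(h, Haplotype):
        return h.diffs_dict()
    return h


def pairwise_differences(h1, h2) -> int:
    """Number of positions at which two haplotypes carry different bases.

    Accepts :class:`~zwturnover.simulate.Haplotype` objects or plain
    position->base diff mappings (relative to the same reference).
    """
    return hap_distance(_diffs_of(h1), _diffs_of(h2))


def nucleotide_diversity(group: Iterable, length: int | None = None) -> float:
    """Mean pairwise difference count over all unordered pairs.

    NaN for groups of fewer than two haplotypes.  Pass ``length`` to scale
    to a per-site value.
    """
    diffs = [_diffs_of(h) for h in group]
    n = len(diffs)
    if n < 2:
        return math.nan
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += hap_distance(diffs[i], diffs[j])
    pi = total / (n * (n - 1) / 2)
    return pi / length if length else pi


def dxy(group_a: Iterable, group_b: Iterable, length: int | None = None) -> float:
    """Mean pairwise difference count over all cross pairs (NaN if empty)."""
    da = [_diffs_of(h) for h in group_a]
    db = [_diffs_of(h) for h in group_b]
    if not da or not db:
        return math.nan
    total = sum(hap_distance(x, y) for x in da for y in db)
    d = total / (len(da) * len(db))
    return d / length if length else d


def fst(pi_w: float, pi_z: float, d_between: float) -> float:
    """Fixation index ``1 - mean(pi_w, pi_z) / d_xy`` (NaN when undefined)."""
    if not (math.isfinite(pi_w) and math.isfinite(pi_z) and math.isfinite(d_between)):
        return math.nan
    if d_between == 0:
        return math.nan
    return 1.0 - ((pi_w + pi_z) / 2.0) / d_between


def diversity_from_counts(items) -> DiversityStats:
    """Diversity statistics from (diffs, functional, count) triples.

    Weighted exact computation over distinct haplotypes; equivalent to the
    naive double loop over all chromosomes.
    """
    items = [(dict(d), bool(f), int(c)) for d, f, c in items if c > 0]

    def _within(sub) -> float:
        n = sum(c for _, c in sub)
        if n < 2:
            return math.nan
        total = 0
        for i, (di, ci) in enumerate(sub):
            for dj, cj in sub[i + 1 :]:
                total += ci * cj * hap_distance(di, dj)
        return total / (n * (n - 1) / 2)

    all_ = [(d, c) for d, _, c in items]
    w = [(d, c) for d, f, c in items if f]
    z = [(d, c) for d, f, c in items if not f]
    pi_all = _within(all_)
    pi_w = _within(w)
    pi_z = _within(z)
    n_w = sum(c for _, c in w)
    n_z = sum(c for _, c in z)
    if n_w and n_z:
        cross = sum(
            ci * cj * hap_distance(di, dj) for di, ci in w for dj, cj in z
        )
        d_between = cross / (n_w * n_z)
    else:
        d_between = math.nan
    return DiversityStats(pi_all, pi_w, pi_z, d_between, fst(pi_w, pi_z, d_between))


def segregating_sites(items) -> int:
    """Number of sites at which more than one base segregates."""
    items = [(dict(d), c) for d, f, c in items if c > 0]
    positions = {p for d, _ in items for p in d}
    seg = 0
    for p in positions:
        alleles = {d.get(p, "ref") for d, _ in items}
        seg += len(alleles) > 1
    return seg


# --------------------------------------------------------------------- #
# association statistics


@dataclass
class GenotypeCountTable:
    """Per-sex genotype-class counts at one variant."""

    female: dict[str, int]  # keys: hom_ref, het, hom_alt
    male: dict[str, int]

    CLASSES = ("hom_ref", "het", "hom_alt")

    def __post_init__(self) -> None:
        for row in (self.female, self.male):
            for k in self.CLASSES:
                row.setdefault(k, 0)
                if row[k] < 0:
                    raise ValueError("genotype counts must be >= 0")

    @classmethod
    def from_genotypes(cls, female_gt, male_gt) -> "GenotypeCountTable":
        """Build from arrays of alt-allele counts (0/1/2; <0 = missing)."""

        def _count(gt):
            gt = np.asarray([g for g in gt if g is not None])
            gt = gt[gt >= 0]
            return {
                "hom_ref": int(np.sum(gt == 0)),
                "het": int(np.sum(gt == 1)),
                "hom_alt": int(np.sum(gt == 2)),
            }

        return cls(_count(female_gt), _count(male_gt))

    @property
    def total(self) -> int:
        return sum(self.female.values()) + sum(self.male.values())


@dataclass
class AssociationResult:
    chi2: float
    df: int
    p: float


def genotypic_sex_association(
    table: GenotypeCountTable, mode: str = "het_vs_hom_df1"
) -> AssociationResult:
    """Pearson chi-square of sex against genotype class (no correction).

    ``het_vs_hom_df1`` (default) collapses genotypes to heterozygous vs
    homozygous (2x2, 1 df); ``full_df2`` keeps the genotype classes that
    are observed at least once (up to 2x3, 2 df).  Degenerate tables (a
    zero margin) give NaN.
    """
    if table.total < 1:
        raise ValueError("empty genotype table")
    if mode == "het_vs_hom_df1":
        rows = np.array(
            [
                [table.female["het"], table.female["hom_ref"] + table.female["hom_alt"]],
                [table.male["het"], table.male["hom_ref"] + table.male["hom_alt"]],
            ],
            dtype=float,
        )
    elif mode == "full_df2":
        rows = np.array(
            [
                [table.female[k] for k in GenotypeCountTable.CLASSES],
                [table.male[k] for k in GenotypeCountTable.CLASSES],
            ],
            dtype=float,
        )
        rows = rows[:, rows.sum(axis=0) > 0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    row_tot = rows.sum(axis=1)
    col_tot = rows.sum(axis=0)
    df = (rows.shape[0] - 1) * (rows.shape[1] - 1)
    if df < 1 or np.any(row_tot == 0) or np.any(col_tot == 0):
        return AssociationResult(math.nan, max(df, 0), math.nan)
    expected = np.outer(row_tot, col_tot) / rows.sum()
    chi2 = float(((rows - expected) ** 2 / expected).sum())
    return AssociationResult(chi2, df, float(_chi2_dist.sf(chi2, df)))


def heterogamety_pattern(female_gt, male_gt) -> str:
    """Classify a variant's sex-genotype pattern.

    ``ZW_like``: every female heterozygous, every male homozygous for one
    and the same allele; ``XY_like``: the mirrored pattern; otherwise
    ``none``.  Missing genotypes (< 0 or None) are excluded; a sex with
    no called genotypes raises ``ValueError``.
    """

    def _clean(gt):
        arr = np.asarray([g for g in gt if g is not None])
        arr = arr[arr >= 0]
        if arr.size == 0:
            raise ValueError("all genotypes missing in one sex")
        return arr

    f = _clean(female_gt)
    m = _clean(male_gt)

    def _all_het(x):
        return bool(np.all(x == 1))

    def _all_same_hom(x):
        return bool(np.all(x == 0) or np.all(x == 2))

    if _all_het(f) and _all_same_hom(m):
        return ZW_LIKE
    if _all_het(m) and _all_same_hom(f):
        return XY_LIKE
    return NO_PATTERN


def sex_ratio_chisq(female_count: int, male_count: int) -> tuple[float, float]:
    """1-df chi-square against an equal sex ratio."""
    total = female_count + male_count
    if total <= 0:
        raise ValueError("empty cohort")
    e = total / 2.0
    chi2 = (female_count - e) ** 2 / e + (male_count - e) ** 2 / e
    return float(chi2), float(_chi2_dist.sf(chi2, 1))


def windowed_pi(
    positions,
    genotypes,
    sequence_length: int,
    window_size: int = 10_000,
    ploidy: int = 2,
) -> pd.DataFrame:
    """Nucleotide diversity per nonoverlapping window from allele frequencies.

    ``genotypes`` is an (n_samples, n_sites) array of alt-allele counts.
    Each site contributes ``2 p (1-p) n/(n-1)`` pairwise-difference mass
    (n = number of haplotypes) to the window containing it; windows tile
    from 0 in half-open intervals, so a variant at a window boundary falls
    in the right-hand window.
    """
    positions = np.asarray(positions, dtype=np.int64)
    genotypes = np.atleast_2d(np.asarray(genotypes))
    if positions.size and (positions.min() < 0 or positions.max() >= sequence_length):
        raise ValueError("variant position outside [0, sequence_length)")
    n_windows = max(1, -(-sequence_length // window_size))
    starts = np.arange(n_windows, dtype=np.int64) * window_size
    ends = np.minimum(starts + window_size, sequence_length)
    pi = np.zeros(n_windows)
    if positions.size:
        n_hap = ploidy * genotypes.shape[0]
        p = genotypes.sum(axis=0) / n_hap
        contrib = 2.0 * p * (1.0 - p) * n_hap / (n_hap - 1)
        np.add.at(pi, positions // window_size, contrib)
    return pd.DataFrame({"start": starts, "end": ends, "pi": pi})


def depth_log_ratio(male_depth, female_depth) -> np.ndarray:
    """Per-window ``log2((male + 0.1) / (female + 0.1))``."""
    m = np.asarray(male_depth, dtype=float)
    f = np.asarray(female_depth, dtype=float)
    if np.any(m < 0) or np.any(f < 0):
        raise ValueError("depths must be >= 0")
    return np.log2((m + 0.1) / (f + 0.1))
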