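"""Synthetic inputs: gene models, sex-genotype cohorts, coverage tracks.

The real study system is a short gene segment on an otherwise
undifferentiated ZW chromosome pair, a resequenced cohort in which one
variant is perfectly sex-linked under female heterogamety, and parental
read-depth tracks showing no systematic male/female difference.  None of
the underlying sequences are needed for the method to be exercised, so
this module generates structurally valid stand-ins:

* :func:`generate_gene_model` -- a segment with an exon/intron structure
  satisfying every :class:`~zwturnover.locus.GeneModel` invariant (GT-AG
  introns, an open reading frame ending in a stop, a founding
  splice-donor mutation);
* :func:`generate_sex_genotype_cohort` -- a genotype table with one
  perfectly ZW-linked causal variant (SNP or 4-bp deletion) plus
  sex-independent background SNPs in Hardy-Weinberg proportions;
* :func:`generate_coverage_tracks` -- two iid positive per-window depth
  tracks with a common mean.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .locus import BASES, CODON_TABLE, STOP, GeneModel

_SENSE_CODONS = tuple(c for c, aa in CODON_TABLE.items() if aa != STOP)
_STOP_CODONS = tuple(c for c, aa in CODON_TABLE.items() if aa == STOP)

_MIN_EXON = 30  # bp, per exon
_MIN_INTRON = 8  # bp: GT + interior + AG


@dataclass
class LocusSpec:
    """Shape of a synthetic gene segment."""

    total_length: int = 1678
    n_exons: int = 2
    exon_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.exon_fraction < 1.0:
            raise ValueError("exon_fraction must be in (0, 1)")
        if self.n_exons < 2:
            raise ValueError("need at least two exons (one intron)")
        if self.total_length < self.n_exons * _MIN_EXON + (self.n_exons - 1) * _MIN_INTRON:
            raise ValueError("total_length too short for the requested structure")


def generate_gene_model(spec: LocusSpec) -> GeneModel:
    """Construct a valid gene model matching ``spec`` (deterministic per seed).

    The coding sequence is assembled codon-by-codon from sense codons with
    a terminal stop, split across ``n_exons`` exons; introns open with GT
    and close with AG; the founding sex-determining mutation is the G>A
    change at the first intron's donor dinucleotide.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.total_length
    n_ex = spec.n_exons
    n_in = n_ex - 1

    coding_len = int(round(L * spec.exon_fraction / 3.0)) * 3
    coding_len = max(coding_len, 3 * (n_ex * _MIN_EXON // 3 + 1))
    intron_total = L - coding_len
    if intron_total < n_in * _MIN_INTRON:
        raise ValueError("exon_fraction leaves too little intron")
    if abs(coding_len / L - spec.exon_fraction) > 0.05:
        raise ValueError("exon_fraction not attainable within 5% at this length")

    def _split(total: int, parts: int, minimum: int) -> list[int]:
        """Random composition of ``total`` into ``parts`` each >= minimum."""
        slack = total - parts * minimum
        cuts = np.sort(rng.integers(0, slack + 1, size=parts - 1)) if parts > 1 else []
        pieces = np.diff(np.concatenate(([0], cuts, [slack]))) if parts > 1 else [slack]
        return [minimum + int(p) for p in pieces]

    exon_lens = _split(coding_len, n_ex, _MIN_EXON)
    intron_lens = _split(intron_total, n_in, _MIN_INTRON)

    n_codons = coding_len // 3
    codons = [str(_SENSE_CODONS[i]) for i in rng.integers(len(_SENSE_CODONS), size=n_codons - 1)]
    codons.append(str(_STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))]))
    cds = "".join(codons)

    seq_parts: list[str] = []
    exon_intervals: list[tuple[int, int]] = []
    pos = 0
    cds_used = 0
    for i, elen in enumerate(exon_lens):
        seq_parts.append(cds[cds_used : cds_used + elen])
        cds_used += elen
        exon_intervals.append((pos, pos + elen))
        pos += elen
        if i < n_in:
            interior = "".join(BASES[k] for k in rng.integers(4, size=intron_lens[i] - 4))
            seq_parts.append("GT" + interior + "AG")
            pos += intron_lens[i]
    reference = "".join(seq_parts)
    assert len(reference) == L

    sd_site = exon_intervals[0][1]  # the G of the first intron's GT donor
    model = GeneModel(
        reference_sequence=reference,
        exon_intervals=tuple(exon_intervals),
        coding_frame_offset=0,
        initial_sd_site=sd_site,
        initial_sd_alt_base="A",
    )
    violations = model.validate()
    if violations:  # pragma: no cover - construction guarantees validity
        raise AssertionError(f"generated model violates invariants: {violations}")
    return model


# --------------------------------------------------------------------- #
# cohorts


@dataclass
class CohortSpec:
    """Shape of a synthetic sex-genotype cohort."""

    n_females: int = 45
    n_males: int = 37
    n_background_snps: int = 100
    freq_low: float = 0.05
    freq_high: float = 0.5
    missingness: float = 0.0
    causal_variant_kind: str = "snp"  # or "deletion"
    region_length: int = 1_000_000
    chrom: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_females < 0 or self.n_males < 0 or self.n_background_snps < 0:
            raise ValueError("counts must be >= 0")
        if self.causal_variant_kind not in ("snp", "deletion"):
            raise ValueError("causal_variant_kind must be 'snp' or 'deletion'")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must be in [0, 1)")


@dataclass
class Cohort:
    """Genotype table plus truth record.

    ``genotypes``: DataFrame (variants x samples) of alt-allele counts
    (0/1/2, -1 missing).  ``variants``: chrom/pos (0-based)/ref/alt.
    ``sex``: per-sample 'F'/'M'.  ``truth``: the causal variant's record.
    """

    variants: pd.DataFrame
    genotypes: pd.DataFrame
    sex: pd.Series
    truth: dict

    def genotypes_by_sex(self, index) -> tuple[np.ndarray, np.ndarray]:
        row = self.genotypes.loc[index].to_numpy()
        is_f = (self.sex == "F").to_numpy()
        return row[is_f], row[~is_f]


def generate_sex_genotype_cohort(spec: CohortSpec) -> Cohort:
    """Cohort with one perfectly ZW-linked causal variant.

    Every female is heterozygous and every male homozygous for the derived
    (reference-assembly) allele at the causal variant; background SNPs are
    drawn independently of sex in Hardy-Weinberg proportions with allele
    frequencies uniform on [freq_low, freq_high].
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_females + spec.n_males
    samples = [f"F{i + 1:03d}" for i in range(spec.n_females)] + [
        f"M{i + 1:03d}" for i in range(spec.n_males)
    ]
    sex = pd.Series(["F"] * spec.n_females + ["M"] * spec.n_males, index=samples)

    causal_pos = spec.region_length // 2
    if spec.causal_variant_kind == "snp":
        ref, alt = "A", "G"  # alt = the W-linked, female-restricted allele
    else:
        ref, alt = "G", "GGACC"  # W carries a 4-bp insertion relative to the Z-type reference

    all_pos = {causal_pos}
    while len(all_pos) < spec.n_background_snps + 1:
        all_pos.update(
            int(p)
            for p in rng.integers(0, spec.region_length, size=spec.n_background_snps)
        )
    bg_pos = sorted(all_pos - {causal_pos})[: spec.n_background_snps]

    rows = [(spec.chrom, causal_pos, ref, alt, "causal")]
    gts = [np.concatenate([np.ones(spec.n_females, dtype=np.int8),
                           np.zeros(spec.n_males, dtype=np.int8)])]
    ref_alt = [("A", "C"), ("C", "T"), ("G", "A"), ("T", "G")]
    for p in bg_pos:
        f = rng.uniform(spec.freq_low, spec.freq_high)
        gts.append(rng.binomial(2, f, size=n).astype(np.int8))
        r, a = ref_alt[int(rng.integers(4))]
        rows.append((spec.chrom, p, r, a, "background"))

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "kind"])
    order = variants["pos"].argsort(kind="stable").to_numpy()
    variants = variants.iloc[order].reset_index(drop=True)
    gmat = np.vstack(gts)[order]
    if spec.missingness > 0:
        mask = rng.random(gmat.shape) < spec.missingness
        gmat = np.where(mask, np.int8(-1), gmat)
    genotypes = pd.DataFrame(gmat, columns=samples)
    truth = {
        "chrom": spec.chrom,
        "pos": causal_pos,
        "ref": ref,
        "alt": alt,
        "kind": spec.causal_variant_kind,
        "index": int(np.flatnonzero(variants["kind"] == "causal")[0]),
    }
    return Cohort(variants, genotypes, sex, truth)


# preset cohort shapes used in worked examples
COHORT_PRESETS: dict[str, CohortSpec] = {
    "golden-pompano": CohortSpec(n_females=45, n_males=37, causal_variant_kind="snp"),
    "florida-pompano": CohortSpec(n_females=14, n_males=7, causal_variant_kind="deletion"),
}


# --------------------------------------------------------------------- #
# coverage tracks


def generate_coverage_tracks(
    n_windows: int, mean_depth: float, noise_sd: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Male and female per-window mean depths with no systematic difference.

    Both tracks are iid positive (gamma) noise around ``mean_depth``, so
    the expected log2 depth ratio is exactly zero in every window.
    ``noise_sd = 0`` gives constant tracks.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_sd == 0:
        track = np.full(n_windows, float(mean_depth))
        return track.copy(), track.copy()
    shape = (mean_depth / noise_sd) ** 2
    scale = noise_sd**2 / mean_depth
    male = rng.gamma(shape, scale, size=n_windows)
    female = rng.gamma(shape, scale, size=n_windows)
    return male, female
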