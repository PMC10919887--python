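"""Gene-segment model and point-mutation effect classification.

The simulator tracks a short genomic segment containing a gene that is
essential for female development under female heterogamety (ZW): a
chromosome whose copy of the gene is fully functional behaves as W, a
chromosome carrying any loss-of-function (LOF) change behaves as Z.  This
module defines the annotated reference segment (:class:`GeneModel`) and the
rule that decides whether a single base change knocks the gene out.

Classification is always made against the *reference* codon: the effect of
a change is a pure function of ``(position, new_base)``, which allows the
full effect table to be precomputed once per model.  A change is LOF when
it is missense, nonsense, or disrupts a splice donor/acceptor dinucleotide;
synonymous and intronic changes are neutral.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STOP = "*"

# standard genetic code, codon string -> amino acid ('*' for stop)
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _c in standard_dna_table.stop_codons:
    CODON_TABLE[_c] = STOP


class EffectCategory(str, Enum):
    """Functional category of a single-base substitution."""

    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"


LOF_CATEGORIES = frozenset(
    {EffectCategory.MISSENSE, EffectCategory.NONSENSE, EffectCategory.SPLICE_SITE}
)

# compact integer codes for the precomputed effect table
_CAT_CODES = {
    EffectCategory.INTRONIC: 0,
    EffectCategory.SYNONYMOUS: 1,
    EffectCategory.MISSENSE: 2,
    EffectCategory.NONSENSE: 3,
    EffectCategory.SPLICE_SITE: 4,
}
_CODE_CATS = {v: k for k, v in _CAT_CODES.items()}


@dataclass(frozen=True)
class MutationEffect:
    """Effect of a single base substitution relative to the reference."""

    category: EffectCategory

    @property
    def lof(self) -> bool:
        return self.category in LOF_CATEGORIES


@dataclass
class GeneModel:
    """Annotated reference segment against which mutations are classified.

    Parameters
    ----------
    reference_sequence
        Ancestral (functional, W-type) sequence, bases A/C/G/T.
    exon_intervals
        Sorted, non-overlapping 0-based half-open intervals.  Gaps between
        consecutive exons are introns and must open with ``GT`` and close
        with ``AG``.
    coding_frame_offset
        Offset (0-2) of the reading frame within the spliced exon sequence.
    initial_sd_site
        Position of the founding sex-determining mutation; must fall in the
        first intron's donor dinucleotide.
    initial_sd_alt_base
        Derived base at that site (must classify as LOF).
    splice_donor_positions, splice_acceptor_positions
        First base of each intron's GT / of each intron's terminal AG.
        Derived from ``exon_intervals`` when not given.
    """

    reference_sequence: str
    exon_intervals: tuple[tuple[int, int], ...]
    initial_sd_site: int
    initial_sd_alt_base: str
    coding_frame_offset: int = 0
    splice_donor_positions: tuple[int, ...] = ()
    splice_acceptor_positions: tuple[int, ...] = ()
    _effect_table: np.ndarray | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.reference_sequence = str(self.reference_sequence).upper()
        self.exon_intervals = tuple((int(a), int(b)) for a, b in self.exon_intervals)
        if not self.splice_donor_positions:
            self.splice_donor_positions = tuple(s for s, _ in self.introns)
            self.splice_acceptor_positions = tuple(e - 2 for _, e in self.introns)
        else:
            self.splice_donor_positions = tuple(self.splice_donor_positions)
            self.splice_acceptor_positions = tuple(self.splice_acceptor_positions)

    # ------------------------------------------------------------------ #
    # structure

    @property
    def total_length(self) -> int:
        return len(self.reference_sequence)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons (0-based half-open)."""
        out = []
        for (_, e1), (s2, _) in zip(self.exon_intervals, self.exon_intervals[1:]):
            out.append((e1, s2))
        return tuple(out)

    @property
    def splice_positions(self) -> frozenset[int]:
        """All positions inside a donor or acceptor dinucleotide."""
        pos: set[int] = set()
        for p in self.splice_donor_positions:
            pos.update((p, p + 1))
        for p in self.splice_acceptor_positions:
            pos.update((p, p + 1))
        return frozenset(pos)

    def spliced_sequence(self) -> str:
        return "".join(self.reference_sequence[a:b] for a, b in self.exon_intervals)

    def coding_sequence(self) -> str:
        return self.spliced_sequence()[self.coding_frame_offset :]

    # ------------------------------------------------------------------ #
    # classification

    def _build_effect_table(self) -> np.ndarray:
        """Category code for every (position, base) pair; -1 on the reference base."""
        L = self.total_length
        ref = self.reference_sequence
        table = np.full((L, 4), _CAT_CODES[EffectCategory.INTRONIC], dtype=np.int8)

        # map each coding position in the genome to (codon index, offset)
        spliced_pos = []  # genome coordinate of each spliced base
        for a, b in self.exon_intervals:
            spliced_pos.extend(range(a, b))
        coding_pos = spliced_pos[self.coding_frame_offset :]
        cds = self.coding_sequence()
        n_codons = len(cds) // 3

        pos_to_codon: dict[int, tuple[int, int]] = {}
        for i, g in enumerate(coding_pos[: 3 * n_codons]):
            pos_to_codon[g] = (i // 3, i % 3)

        splice = self.splice_positions
        for p in range(L):
            for b in BASES:
                if b == ref[p]:
                    table[p, _BASE_INDEX[b]] = -1
                    continue
                if p in splice:
                    cat = EffectCategory.SPLICE_SITE
                elif p in pos_to_codon:
                    ci, off = pos_to_codon[p]
                    codon = cds[3 * ci : 3 * ci + 3]
                    alt = codon[:off] + b + codon[off + 1 :]
                    aa_ref = CODON_TABLE[codon]
                    aa_alt = CODON_TABLE[alt]
                    if aa_alt == aa_ref:
                        cat = EffectCategory.SYNONYMOUS
                    elif aa_alt == STOP:
                        cat = EffectCategory.NONSENSE
                    else:
                        # includes loss of the terminal stop codon
                        cat = EffectCategory.MISSENSE
                else:
                    cat = EffectCategory.INTRONIC
                table[p, _BASE_INDEX[b]] = _CAT_CODES[cat]
        return table

    @property
    def effect_table(self) -> np.ndarray:
        if self._effect_table is None:
            self._effect_table = self._build_effect_table()
        return self._effect_table

    def classify(self, position: int, new_base: str) -> MutationEffect:
        """Classify a substitution of ``new_base`` at ``position``.

        Raises ``ValueError`` for out-of-range positions or a base equal to
        the reference base.
        """
        if not 0 <= position < self.total_length:
            raise ValueError(f"position {position} outside [0, {self.total_length})")
        new_base = new_base.upper()
        if new_base not in _BASE_INDEX:
            raise ValueError(f"invalid base {new_base!r}")
        code = self.effect_table[position, _BASE_INDEX[new_base]]
        if code < 0:
            raise ValueError(
                f"base {new_base} equals the reference base at position {position}"
            )
        return MutationEffect(_CODE_CATS[int(code)])

    def is_lof(self, position: int, new_base: str) -> bool:
        return self.classify(position, new_base).lof

    def lof_positions(self, diffs: Mapping[int, str]) -> list[int]:
        """Positions in ``diffs`` whose change is loss-of-function."""
        table = self.effect_table
        out = []
        for p, b in diffs.items():
            code = table[p, _BASE_INDEX[b]]
            if code < 0:
                raise ValueError(f"diff at {p} equals the reference base")
            if _CODE_CATS[int(code)] in LOF_CATEGORIES:
                out.append(p)
        return out

    # ------------------------------------------------------------------ #
    # validation

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errs: list[str] = []
        L = self.total_length
        if any(c not in _BASE_INDEX for c in self.reference_sequence):
            errs.append("reference sequence contains non-ACGT characters")
        prev_end = None
        for a, b in self.exon_intervals:
            if not (0 <= a < b <= L):
                errs.append(f"exon ({a},{b}) outside [0,{L})")
            if prev_end is not None and a < prev_end:
                errs.append("exon intervals unsorted or overlapping")
            prev_end = b
        for s, e in self.introns:
            if self.reference_sequence[s : s + 2] != "GT":
                errs.append(f"intron at {s} does not open with GT")
            if self.reference_sequence[e - 2 : e] != "AG":
                errs.append(f"intron ending at {e} does not close with AG")
        cds = self.coding_sequence()
        if len(cds) % 3 != 0:
            errs.append("coding sequence length not divisible by 3")
        else:
            aas = [CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3)]
            if STOP in aas[:-1]:
                errs.append("internal stop codon in coding sequence")
            if not aas or aas[-1] != STOP:
                errs.append("coding sequence does not end with a stop codon")
        if not self.introns:
            errs.append("gene model has no intron")
        else:
            d0 = self.introns[0][0]
            if self.initial_sd_site not in (d0, d0 + 1):
                errs.append("initial SD site not in the first intron's donor dinucleotide")
        try:
            if not self.classify(self.initial_sd_site, self.initial_sd_alt_base).lof:
                errs.append("initial SD change does not classify as LOF")
        except ValueError as exc:
            errs.append(f"initial SD change invalid: {exc}")
        return errs

    # ------------------------------------------------------------------ #
    # serialization

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "total_length": self.total_length,
            "exon_intervals": [list(iv) for iv in self.exon_intervals],
            "coding_frame_offset": self.coding_frame_offset,
            "splice_donor_positions": list(self.splice_donor_positions),
            "splice_acceptor_positions": list(self.splice_acceptor_positions),
            "initial_sd_site": self.initial_sd_site,
            "initial_sd_alt_base": self.initial_sd_alt_base,
        }

    def save(self, model_path: str | Path, fasta_path: str | Path) -> None:
        """Write the structure as JSON and the reference sequence as FASTA."""
        Path(model_path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        rec = SeqRecord(
            Seq(self.reference_sequence), id="segment", description="reference (W-type)"
        )
        SeqIO.write([rec], str(fasta_path), "fasta")

    @classmethod
    def load(cls, model_path: str | Path, fasta_path: str | Path) -> "GeneModel":
        meta = json.loads(Path(model_path).read_text())
        major = int(meta.get("format_version", 0))
        if major != 1:
            raise ValueError(f"unsupported gene-model format version {major}")
        rec = next(SeqIO.parse(str(fasta_path), "fasta"))
        seq = str(rec.seq).upper()
        if len(seq) != meta["total_length"]:
            raise ValueError("FASTA length does not match the model's total_length")
        return cls(
            reference_sequence=seq,
            exon_intervals=tuple(tuple(iv) for iv in meta["exon_intervals"]),
            coding_frame_offset=meta["coding_frame_offset"],
            splice_donor_positions=tuple(meta["splice_donor_positions"]),
            splice_acceptor_positions=tuple(meta["splice_acceptor_positions"]),
            initial_sd_site=meta["initial_sd_site"],
            initial_sd_alt_base=meta["initial_sd_alt_base"],
        )

    def exons_to_bed(self, chrom: str = "segment") -> str:
        """Exon intervals as BED (0-based, half-open) text."""
        return "".join(f"{chrom}\t{a}\t{b}\texon_{i + 1}\n"
                       for i, (a, b) in enumerate(self.exon_intervals))


def classify_site_change(gene_model: GeneModel, position: int, new_base: str) -> MutationEffect:
    """Functional form of :meth:`GeneModel.classify`."""
    return gene_model.classify(position, new_base)


def is_functional(diffs: Mapping[int, str], gene_model: GeneModel) -> bool:
    """True iff no entry of ``diffs`` is loss-of-function.

    ``diffs`` maps positions to the current (non-reference) base; a site
    that has reverted to the reference must carry no entry, so a back
    mutation restores function.
    """
    table = gene_model.effect_table
    for p, b in diffs.items():
        code = table[p, _BASE_INDEX[b]]
        if code < 0:
            raise ValueError(f"diff at position {p} equals the reference base")
        if _CODE_CATS[int(code)] in LOF_CATEGORIES:
            return False
    return True
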