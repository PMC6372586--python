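"""Codon-level consequence annotation on explicit CDS models.

A :class:`TranscriptModel` carries the coding sequence of one gene together
with its genomic exon layout, which is all that is needed to classify a
single-nucleotide substitution as synonymous or non-synonymous and to name
it in protein coordinates (e.g. ``FGFR1 D129A``).  Protein-domain and
mutational-hotspot tables for FGFR1/2/3 are packaged as static TSVs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "ProteinChange",
    "Consequence",
    "AnnotationError",
    "ReferenceMismatchError",
    "UnknownGeneError",
    "annotate_consequence",
    "map_domain",
    "flag_hotspot",
    "load_domains",
    "load_hotspots",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class AnnotationError(ValueError):
    pass


class ReferenceMismatchError(AnnotationError):
    """The supplied reference allele disagrees with the CDS sequence."""


class UnknownGeneError(KeyError):
    pass


class Consequence(enum.Enum):
    """Markers for variants without a codon-level protein change."""

    NON_CODING = "non_coding"
    UNEVALUATED = "unevaluated"  # indels: outside the substitution annotator


@dataclass(frozen=True)
class ProteinChange:
    gene: str
    codon_index: int  # 1-based amino-acid position
    ref_aa: str
    alt_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.alt_aa

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


@dataclass
class TranscriptModel:
    """CDS model: ordered genomic segments plus the spliced coding sequence.

    ``cds_segments`` are 1-based inclusive genomic intervals in ascending
    genomic order; ``cds_sequence`` is given 5'→3' in *transcript*
    orientation, so for a minus-strand gene the first CDS base corresponds
    to the genomically last base of the last segment.
    """

    gene: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    cds_sequence: str

    _cum: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds_sequence = self.cds_sequence.upper()
        total = 0
        self._cum = []
        last_end = 0
        for start, end in self.cds_segments:
            if start > end or start < 1:
                raise AnnotationError(f"bad CDS segment ({start}, {end})")
            if start <= last_end:
                raise AnnotationError("CDS segments must be ascending and disjoint")
            last_end = end
            self._cum.append(total)
            total += end - start + 1
        if total != len(self.cds_sequence):
            raise AnnotationError(
                f"{self.gene}: segment length {total} != CDS length {len(self.cds_sequence)}"
            )
        if total % 3 != 0:
            raise AnnotationError(f"{self.gene}: CDS length {total} not divisible by 3")
        protein = str(Seq(self.cds_sequence).translate())
        if "*" in protein:
            raise AnnotationError(f"{self.gene}: internal stop codon in CDS")

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """0-based CDS index of genomic position ``pos``, or None if intronic
        or outside the CDS footprint."""
        plus_index = None
        for (start, end), cum in zip(self.cds_segments, self._cum):
            if start <= pos <= end:
                plus_index = cum + (pos - start)
                break
        if plus_index is None:
            return None
        if self.strand == "+":
            return plus_index
        return len(self.cds_sequence) - 1 - plus_index

    def cds_to_genomic(self, index: int) -> int:
        """Inverse of :meth:`genomic_to_cds` (0-based CDS index → genomic pos)."""
        n = len(self.cds_sequence)
        if not 0 <= index < n:
            raise IndexError(index)
        plus_index = index if self.strand == "+" else n - 1 - index
        for (start, end), cum in zip(self.cds_segments, self._cum):
            if cum <= plus_index <= cum + (end - start):
                return start + (plus_index - cum)
        raise AssertionError("unreachable: cumulative offsets cover the CDS")


def annotate_consequence(key, model: TranscriptModel):
    """Classify a variant against one transcript model.

    Returns a :class:`ProteinChange` for single-nucleotide substitutions
    inside the CDS, :data:`Consequence.NON_CODING` for positions outside all
    CDS segments, and :data:`Consequence.UNEVALUATED` for indels (the
    hotspot screen concerns substitutions; indels are not interpreted).

    Raises :class:`ReferenceMismatchError` when the reference allele does not
    match the CDS sequence at the mapped position.
    """
    if len(key.ref) != 1 or len(key.alt) != 1:
        return Consequence.UNEVALUATED
    cds_i = model.genomic_to_cds(key.pos)
    if cds_i is None:
        return Consequence.NON_CODING
    ref_t, alt_t = key.ref, key.alt
    if model.strand == "-":
        ref_t = ref_t.translate(_COMPLEMENT)
        alt_t = alt_t.translate(_COMPLEMENT)
    if model.cds_sequence[cds_i] != ref_t:
        raise ReferenceMismatchError(
            f"{model.gene}: CDS has {model.cds_sequence[cds_i]} at index {cds_i}, "
            f"variant ref (transcript strand) is {ref_t}"
        )
    codon_i = cds_i // 3
    codon = model.cds_sequence[3 * codon_i : 3 * codon_i + 3]
    offset = cds_i % 3
    mutant = codon[:offset] + alt_t + codon[offset + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(mutant).translate())
    return ProteinChange(model.gene, codon_i + 1, ref_aa, alt_aa)


# ---------------------------------------------------------------------------
# Packaged domain / hotspot tables


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("fgfrscreen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_domains() -> pd.DataFrame:
    """Protein-domain intervals (gene, domain, aa_start, aa_end) for FGFR1/2/3."""
    return _load_packaged("fgfr_domains.tsv")


def load_hotspots() -> pd.DataFrame:
    """Recurrently mutated codons (gene, codon, note) for FGFR1/2/3."""
    return _load_packaged("fgfr_hotspots.tsv")


def map_domain(gene: str, codon_index: int, domains: pd.DataFrame) -> str:
    """Label of the protein domain containing ``codon_index``, else 'other'."""
    rows = domains[domains["gene"] == gene]
    if rows.empty:
        raise UnknownGeneError(gene)
    hit = rows[(rows["aa_start"] <= codon_index) & (codon_index <= rows["aa_end"])]
    if hit.empty:
        return "other"
    return str(hit.iloc[0]["domain"])


def flag_hotspot(change: ProteinChange, hotspots: pd.DataFrame) -> bool:
    """True iff the changed codon is a known mutational hotspot of its gene."""
    if hotspots.empty:
        return False
    return bool(
        ((hotspots["gene"] == change.gene) & (hotspots["codon"] == change.codon_index)).any()
    )
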