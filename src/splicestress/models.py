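"""Gene and isoform models used by the simulator and the length analyses.

Coordinates are 0-based, half-open. Minus-strand genes store their features
in transcription order, so index 0 of an interval list is always the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

from splicestress.config import InputError

Interval = Tuple[int, int]

UTR3_SPLICING = "Splicing"
UTR3_ALT_POLY = "Alternate3Poly"
UTR3_AMBIGUOUS = "NoAnnotatedDiff/Ambiguous"
UTR3_CLASSES = (UTR3_SPLICING, UTR3_ALT_POLY, UTR3_AMBIGUOUS)


@dataclass
class Isoform:
    isoform_id: str
    transcript_length: int
    utr5_length: int
    cds_length: int
    utr3_length: int
    exon_count: int
    # 3'UTR exon intervals in gene-local coordinates (transcription order)
    utr3_exons: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.transcript_length != self.utr5_length + self.cds_length + self.utr3_length:
            raise InputError(
                f"{self.isoform_id}: transcript length {self.transcript_length} != "
                f"utr5 + cds + utr3 = "
                f"{self.utr5_length + self.cds_length + self.utr3_length}"
            )
        if min(self.utr5_length, self.cds_length, self.utr3_length) < 0:
            raise InputError(f"{self.isoform_id}: negative feature length")


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    isoforms: List[Isoform]
    # intron intervals in gene-local coordinates, disjoint, transcription order
    intron_intervals: List[Interval] = field(default_factory=list)
    chrom: str = "chrS"
    start: int = 0  # genomic start of the gene span
    span: int = 0  # genomic length of the gene span
    # 3'UTR mechanism class the simulator constructed this gene to satisfy;
    # empty for genes read from external annotation
    utr3_class_truth: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = -1
        for s, e in self.intron_intervals:
            if s <= prev_end or e <= s:
                raise InputError(f"{self.gene_id}: intron intervals must be disjoint and ordered")
            prev_end = e
        if self.intron_intervals and self.span:
            if self.intron_intervals[-1][1] > self.span:
                raise InputError(f"{self.gene_id}: intron outside gene span")

    @property
    def end(self) -> int:
        return self.start + self.span

    @property
    def n_isoforms(self) -> int:
        return len(self.isoforms)

    def genomic_intron(self, local: Interval) -> Interval:
        """Map a gene-local (transcription-order) interval to genomic coords."""
        s, e = local
        if self.strand == "+":
            return (self.start + s, self.start + e)
        return (self.end - e, self.end - s)

    def donor_site(self, local_intron: Interval) -> int:
        """Genomic coordinate of the intron's 5' (donor) end."""
        gs, ge = self.genomic_intron(local_intron)
        return gs if self.strand == "+" else ge

    def longest_utr5_index(self) -> int:
        lens = [iso.utr5_length for iso in self.isoforms]
        return int(max(range(len(lens)), key=lens.__getitem__))
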