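"""Genomic annotation models and structural statistics.

Coordinates are GTF-style throughout: 1-based, inclusive on both ends, so an
interval's length is ``end - start + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "longest_orf_length",
    "classify_lncrna_position",
    "structure_summary",
    "gene_level_fpkm",
]

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between two intervals on one chromosome; 0 if they overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap is defined within one chromosome only")
        if self.start <= other.end and other.start <= self.end:
            return 0
        if self.end < other.start:
            return other.start - self.end - 1
        return self.start - other.end - 1


@dataclass
class TranscriptModel:
    """An exon-resolved transcript.

    ``biotype`` starts as ``mRNA`` or ``lncRNA_candidate``; candidates that
    survive identification are re-labelled with their positional class
    (``lincRNA`` / ``antisense_lncRNA`` / ``intronic_lncRNA``).
    """

    transcript_id: str
    gene_id: str
    biotype: str
    exons: list[GenomicInterval] = field(default_factory=list)
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        self.exons.sort(key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"transcript {self.transcript_id}: sequence length "
                f"{len(self.sequence)} != exon-chain length {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )


@dataclass
class GeneModel:
    gene_id: str
    span: GenomicInterval
    transcript_ids: list[str] = field(default_factory=list)
    biotype: str = "mRNA"


def longest_orf_length(sequence: str) -> int:
    """Length in nt of the longest complete ORF on the three forward frames.

    An ORF runs from an ATG to the first in-frame stop (TAA/TAG/TGA),
    measured from the A of the ATG through the last base of the stop codon.
    Returns 0 when no complete ORF exists. Codons containing ``N`` are
    treated as unusable: they neither start nor terminate an ORF and any
    open reading passing through one is discarded.
    """
    seq = sequence.upper()
    n = len(seq)
    best = 0
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                # any reading spanning this codon is unusable: restart
                start = None
                continue
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOP_CODONS:
                best = max(best, i + 3 - start)
                start = None
    return best


def classify_lncrna_position(
    lnc: TranscriptModel,
    genes: Iterable[GeneModel],
    mrnas: Iterable[TranscriptModel],
) -> str:
    """Positional class of a lncRNA relative to protein-coding annotation.

    Precedence: ``antisense_lncRNA`` when any lncRNA exon overlaps an
    opposite-strand mRNA exon; else ``intronic_lncRNA`` when the lncRNA span
    lies entirely inside a gene span without same-strand exon overlap; else
    ``lincRNA`` (intergenic).
    """
    span = lnc.span
    same_strand_exon_overlap = False
    for t in mrnas:
        if t.chrom != span.chrom:
            continue
        t_span = t.span
        if not (t_span.start <= span.end and span.start <= t_span.end):
            continue
        for te in t.exons:
            for le in lnc.exons:
                if le.start <= te.end and te.start <= le.end:
                    if te.strand != le.strand:
                        return "antisense_lncRNA"
                    same_strand_exon_overlap = True
    if not same_strand_exon_overlap:
        for g in genes:
            gs = g.span
            if gs.chrom == span.chrom and gs.start <= span.start and span.end <= gs.end:
                return "intronic_lncRNA"
    return "lincRNA"


def structure_summary(transcripts: Sequence[TranscriptModel]) -> pd.DataFrame:
    """Per-biotype medians and histogram-ready values of exon count,
    transcript length and longest-ORF length.

    ORF length is computed only for transcripts that carry a sequence.
    """
    rows = []
    for t in transcripts:
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "biotype": t.biotype,
                "exon_count": t.exon_count,
                "length_nt": t.length,
                "orf_length_nt": (
                    longest_orf_length(t.sequence) if t.sequence is not None else np.nan
                ),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["transcript_id", "biotype", "exon_count", "length_nt", "orf_length_nt"]
        )
    return pd.DataFrame(rows).sort_values("transcript_id").reset_index(drop=True)


def structure_medians(summary: pd.DataFrame) -> pd.DataFrame:
    """Median exon count / length / ORF length per biotype."""
    if summary.empty:
        return pd.DataFrame()
    return summary.groupby("biotype")[["exon_count", "length_nt", "orf_length_nt"]].median()


def gene_level_fpkm(expr, transcripts: Sequence[TranscriptModel]):
    """Aggregate a transcript-level FPKM matrix to genes by summation.

    Gene FPKM per sample is the sum of its member transcripts' FPKMs.
    Output gene order is lexicographic; every expression feature must map to
    a gene through ``transcripts``.
    """
    from .expression import ExpressionMatrix

    t2g: Mapping[str, str] = {t.transcript_id: t.gene_id for t in transcripts}
    missing = [f for f in expr.feature_ids if f not in t2g]
    if missing:
        raise ValueError(
            "features without a gene_id mapping: " + ", ".join(sorted(missing)[:10])
        )
    gene_of = pd.Series({f: t2g[f] for f in expr.feature_ids})
    values = expr.values.groupby(gene_of).sum().sort_index()
    return ExpressionMatrix(values=values, sample_meta=expr.sample_meta.copy())
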