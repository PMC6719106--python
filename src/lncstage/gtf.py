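"""Minimal GTF reader/writer for the gene/transcript/exon dialect used here.

Only ``exon`` features are required to reconstruct transcripts; ``gene`` and
``transcript`` lines are accepted and used for gene biotype metadata. The
reader enforces the attribute keys ``gene_id`` and ``transcript_id`` and
reports malformed input with its line number.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

from .annotation import GeneModel, GenomicInterval, TranscriptModel

__all__ = ["read_gtf", "write_gtf"]

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


class GtfParseError(ValueError):
    pass


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path) -> tuple[dict[str, GeneModel], dict[str, TranscriptModel]]:
    """Parse a GTF file into gene and transcript models keyed by id."""
    exons: dict[str, list[GenomicInterval]] = {}
    t_gene: dict[str, str] = {}
    t_biotype: dict[str, str] = {}
    gene_biotype: dict[str, str] = {}
    seen_transcript_lines: set[str] = set()

    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields, got {len(parts)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if end < start:
                raise GtfParseError(f"line {lineno}: end {end} < start {start}")
            attrs = _parse_attributes(attr_s)
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            if feature == "gene":
                gene_biotype[gid] = attrs.get("gene_biotype", "mRNA")
                continue
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: missing transcript_id attribute")
            tid = attrs["transcript_id"]
            if feature == "transcript":
                if tid in seen_transcript_lines:
                    raise GtfParseError(f"line {lineno}: duplicate transcript_id {tid!r}")
                seen_transcript_lines.add(tid)
                t_biotype[tid] = attrs.get("transcript_biotype", gene_biotype.get(gid, "mRNA"))
            elif feature != "exon":
                continue
            if tid in t_gene and t_gene[tid] != gid:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid!r} assigned to two genes"
                )
            t_gene[tid] = gid
            if feature == "exon":
                try:
                    iv = GenomicInterval(chrom, start, end, strand)
                except ValueError as exc:
                    raise GtfParseError(f"line {lineno}: {exc}") from None
                exons.setdefault(tid, []).append(iv)

    transcripts: dict[str, TranscriptModel] = {}
    for tid, ivs in exons.items():
        gid = t_gene[tid]
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            biotype=t_biotype.get(tid, gene_biotype.get(gid, "mRNA")),
            exons=ivs,
        )

    genes: dict[str, GeneModel] = {}
    for tid in sorted(transcripts):
        t = transcripts[tid]
        g = genes.get(t.gene_id)
        if g is None:
            genes[t.gene_id] = GeneModel(
                gene_id=t.gene_id,
                span=t.span,
                transcript_ids=[tid],
                biotype=gene_biotype.get(t.gene_id, t.biotype),
            )
        else:
            g.transcript_ids.append(tid)
            g.span = GenomicInterval(
                g.span.chrom,
                min(g.span.start, t.span.start),
                max(g.span.end, t.span.end),
                g.span.strand,
            )
    return genes, transcripts


def write_gtf(path, genes: Iterable[GeneModel], transcripts: Iterable[TranscriptModel]) -> None:
    transcripts = list(transcripts)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(Path(path), "w") as fh:
        for g in sorted(genes, key=lambda g: g.gene_id):
            fh.write(
                "\t".join(
                    [
                        g.span.chrom,
                        "lncstage",
                        "gene",
                        str(g.span.start),
                        str(g.span.end),
                        ".",
                        g.span.strand,
                        ".",
                        f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";',
                    ]
                )
                + "\n"
            )
            for t in sorted(by_gene.get(g.gene_id, []), key=lambda t: t.transcript_id):
                base = f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; transcript_biotype "{t.biotype}";'
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            "lncstage",
                            "transcript",
                            str(t.span.start),
                            str(t.span.end),
                            ".",
                            t.strand,
                            ".",
                            base,
                        ]
                    )
                    + "\n"
                )
                for e in t.exons:
                    fh.write(
                        "\t".join(
                            [
                                e.chrom,
                                "lncstage",
                                "exon",
                                str(e.start),
                                str(e.end),
                                ".",
                                e.strand,
                                ".",
                                base,
                            ]
                        )
                        + "\n"
                    )
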