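"""GTF/GFF3 and BED readers, a GTF writer, and the tabular alignment reader.

GTF/GFF coordinates are 1-based inclusive on disk and converted to 0-based
half-open in memory; BED is 0-based half-open already. Only ``exon``
features are used to build transcripts — transcript/gene container lines
are accepted and ignored, which keeps the reader tolerant of both GTF
attribute syntax (``key "value";``) and GFF3 syntax (``key=value``).
"""

from __future__ import annotations

import re
from collections import OrderedDict
from pathlib import Path
from typing import Iterable

from .models import AlignmentHit, GeneModel, GenomicTranscript

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"(\w+)=([^;]+)")


def _parse_attributes(field: str) -> dict[str, str]:
    if "=" in field and '"' not in field:
        attrs = dict(_GFF3_ATTR.findall(field))
        # GFF3 links exons to transcripts via Parent=
        if "Parent" in attrs and "transcript_id" not in attrs:
            attrs["transcript_id"] = attrs["Parent"].split(",")[0]
        return attrs
    return dict(_GTF_ATTR.findall(field))


def read_transcripts(path: str | Path) -> list[GenomicTranscript]:
    """Read transcripts (exon chains) from a GTF or GFF3 file."""
    exons: "OrderedDict[str, dict]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, ftype, start, end, _score, strand, _frame, attr = fields
            if ftype != "exon":
                continue
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id/Parent")
            rec = exons.setdefault(
                tid,
                {"chrom": chrom, "strand": strand, "gene_id": attrs.get("gene_id"), "exons": []},
            )
            rec["exons"].append((int(start) - 1, int(end)))
    out = []
    for tid, rec in exons.items():
        out.append(
            GenomicTranscript(
                id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                gene_id=rec["gene_id"],
            )
        )
    return out


def read_genes(path: str | Path) -> list[GeneModel]:
    """Read a reference annotation and group its transcripts into gene models.

    Transcripts lacking a ``gene_id`` attribute form single-transcript genes
    named after the transcript.
    """
    by_gene: "OrderedDict[str, list[GenomicTranscript]]" = OrderedDict()
    for t in read_transcripts(path):
        by_gene.setdefault(t.gene_id or t.id, []).append(t)
    return [GeneModel.from_transcripts(g, ts) for g, ts in by_gene.items()]


def write_gtf(transcripts: Iterable[GenomicTranscript], path: str | Path, source: str = "plantlnc") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            gene = t.gene_id or t.id
            attrs = f'gene_id "{gene}"; transcript_id "{t.id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED3/BED6 intervals as (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs at least 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from e
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            out.append((fields[0], start, end, name))
    return out


def read_alignment_hits(path: str | Path) -> list[AlignmentHit]:
    """Read 12-column tabular alignment hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore); extra trailing
    columns are tolerated."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                evalue = float(fields[10])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from e
            hits.append(
                AlignmentHit(fields[0], fields[1], pident, evalue, tuple(fields[11:]))
            )
    return hits
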