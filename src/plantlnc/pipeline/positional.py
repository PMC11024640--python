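"""Six-way positional classification of identified lncRNAs.

Each lncRNA receives exactly one class, the first match in a fixed
precedence order (overlap classes before proximal classes, divergent
promoter-sharing before plain upstream):

1. ANTISENSE_EXONIC — an exon overlaps a gene exon on the opposite strand.
2. INTRONIC — the lncRNA overlaps a gene's span with no exon-exon overlap
   (either strand), i.e. it lies within the gene's introns.
3. BIDIRECTIONAL — no overlap; the lncRNA sits on the opposite strand of a
   gene, wholly on that gene's 5' side (so the two are transcribed
   divergently, head-to-head), with its TSS within the window of the gene
   TSS.
4. UPSTREAM — no overlap; the lncRNA lies wholly 5' of a gene with the
   distance from its 3' end to the gene TSS within the window.
5. DOWNSTREAM — no overlap; wholly 3' of a gene with the distance from the
   gene TTS to the lncRNA 5' end within the window.
6. INTERGENIC — none of the above.

The partner gene is the one triggering the class; ties are broken by
smallest distance, then lexicographic gene id. Upstream/downstream partners
may lie on either strand (the proximity rules are not strand-restricted);
the divergent case is captured first by rule 3.
"""

from __future__ import annotations

from typing import Sequence

from intervaltree import IntervalTree

from .models import ClassifiedLncRNA, GeneModel, GenomicTranscript, LncClass, PipelineConfig


def _exon_overlap(a: GenomicTranscript, g: GeneModel) -> bool:
    # merge-scan: both exon lists are sorted
    exons_g = list(g.exons)
    i = j = 0
    exons_a = list(a.exons)
    while i < len(exons_a) and j < len(exons_g):
        s1, e1 = exons_a[i]
        s2, e2 = exons_g[j]
        if min(e1, e2) > max(s1, s2):
            return True
        if e1 < e2:
            i += 1
        else:
            j += 1
    return False


def _span_overlap(t: GenomicTranscript, g: GeneModel) -> bool:
    return min(t.end, g.end) > max(t.start, g.start)


def classify_positions(
    lncs: Sequence[GenomicTranscript],
    genes: Sequence[GeneModel],
    cfg: PipelineConfig | None = None,
) -> list[ClassifiedLncRNA]:
    """Assign each lncRNA its positional class against the reference genes.

    With no genes every lncRNA is INTERGENIC. The classes partition the
    input: every transcript is assigned exactly one class.
    """
    cfg = cfg or PipelineConfig()
    window = cfg.window_bp
    span_trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        span_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[ClassifiedLncRNA] = []
    for t in lncs:
        tree = span_trees.get(t.chrom)
        overlapping = (
            sorted((iv.data for iv in tree.overlap(t.start, t.end)), key=lambda g: g.gene_id)
            if tree
            else []
        )
        # rule 1: antisense exonic
        partners = [g for g in overlapping if g.strand != t.strand and _exon_overlap(t, g)]
        if partners:
            out.append(
                ClassifiedLncRNA(t.id, LncClass.ANTISENSE_EXONIC, partners[0].gene_id, 0)
            )
            continue
        # rule 2: intronic (span overlap, no exon-exon overlap on either strand)
        partners = [g for g in overlapping if not _exon_overlap(t, g)]
        if partners:
            out.append(ClassifiedLncRNA(t.id, LncClass.INTRONIC, partners[0].gene_id, 0))
            continue
        if overlapping:
            # same-strand exon overlap with every overlapped gene: falls through
            # to the proximity rules against non-overlapping genes only
            pass
        nearby = [
            g
            for g in by_chrom.get(t.chrom, [])
            if not _span_overlap(t, g)
        ]
        # rule 3: bidirectional (divergent, promoter-sharing)
        cands: list[tuple[int, str, GeneModel]] = []
        for g in nearby:
            if g.strand == t.strand:
                continue
            if g.strand == "+" and t.strand == "-" and t.end <= g.start:
                d = g.tss - t.tss  # t.tss is t.end
            elif g.strand == "-" and t.strand == "+" and t.start >= g.end:
                d = t.tss - g.tss
            else:
                continue
            if 0 <= d <= window:
                cands.append((d, g.gene_id, g))
        if cands:
            d, gid, _ = min(cands)
            out.append(ClassifiedLncRNA(t.id, LncClass.BIDIRECTIONAL, gid, d))
            continue
        # rule 4: upstream (lnc wholly 5' of the gene, 3' end near the TSS)
        cands = []
        for g in nearby:
            if g.strand == "+" and t.end <= g.start:
                three_prime = t.end if t.strand == "+" else t.start
                d = g.tss - three_prime
            elif g.strand == "-" and t.start >= g.end:
                three_prime = t.end if t.strand == "+" else t.start
                d = three_prime - g.tss
            else:
                continue
            if 0 <= d <= window:
                cands.append((d, g.gene_id, g))
        if cands:
            d, gid, _ = min(cands)
            out.append(ClassifiedLncRNA(t.id, LncClass.UPSTREAM, gid, d))
            continue
        # rule 5: downstream (lnc wholly 3' of the gene, 5' end near the TTS)
        cands = []
        for g in nearby:
            if g.strand == "+" and t.start >= g.end:
                five_prime = t.start if t.strand == "+" else t.end
                d = five_prime - g.tts
            elif g.strand == "-" and t.end <= g.start:
                five_prime = t.start if t.strand == "+" else t.end
                d = g.tts - five_prime
            else:
                continue
            if 0 <= d <= window:
                cands.append((d, g.gene_id, g))
        if cands:
            d, gid, _ = min(cands)
            out.append(ClassifiedLncRNA(t.id, LncClass.DOWNSTREAM, gid, d))
            continue
        out.append(ClassifiedLncRNA(t.id, LncClass.INTERGENIC, None, 0))
    return out
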