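"""Candidate filtering and protein-homology filtering.

``filter_candidates`` applies the pre-classification filter: transcripts
shorter than the minimum exonic length are removed, monoexonic transcripts
are handled per the configured mode, and transcripts whose exons overlap a
known mRNA exon on the same strand by at least 1 bp are removed. Each
removed transcript gets exactly one removal reason — the first failing rule
in the order length, monoexonic, sense-overlap.

``homology_filter`` flags candidates with any protein hit above the
identity cutoff (strict >) and below the e-value cutoff (strict <) as
potential coding transcripts and excludes them; candidates without hits are
kept.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .models import AlignmentHit, GeneModel, GenomicTranscript, MonoexonicMode, PipelineConfig

REASON_LENGTH = "length"
REASON_MONOEXONIC = "monoexonic"
REASON_SENSE_OVERLAP = "sense_overlap"


def _exon_trees(genes: Sequence[GeneModel]) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        tree = trees.setdefault((g.chrom, g.strand), IntervalTree())
        for s, e in g.exons:
            tree.addi(s, e)
    return trees


def _overlaps_exon(
    trees: dict[tuple[str, str], IntervalTree], t: GenomicTranscript, strand: str
) -> bool:
    tree = trees.get((t.chrom, strand))
    if tree is None:
        return False
    return any(tree.overlap(s, e) for s, e in t.exons)


_OPPOSITE = {"+": "-", "-": "+"}


def filter_candidates(
    candidates: Sequence[GenomicTranscript],
    reference: Sequence[GeneModel],
    cfg: PipelineConfig | None = None,
) -> tuple[list[GenomicTranscript], list[tuple[str, str]]]:
    """Length / monoexonic / sense-overlap filter.

    Returns the kept transcripts and a removal log of ``(transcript_id,
    reason)`` pairs. Candidates on chromosomes absent from the reference are
    treated as having no reference context (a warning is emitted once).
    """
    cfg = cfg or PipelineConfig()
    trees = _exon_trees(reference)
    ref_chroms = {g.chrom for g in reference}
    warned: set[str] = set()
    kept: list[GenomicTranscript] = []
    removed: list[tuple[str, str]] = []
    for t in candidates:
        if t.chrom not in ref_chroms and t.chrom not in warned and ref_chroms:
            warnings.warn(
                f"transcript {t.id} on chromosome {t.chrom!r} absent from the reference; "
                "treated as having no reference context",
                stacklevel=2,
            )
            warned.add(t.chrom)
        if t.exonic_length < cfg.min_length_nt:
            removed.append((t.id, REASON_LENGTH))
            continue
        if t.is_monoexonic:
            mode = cfg.monoex_mode
            if mode is MonoexonicMode.DISCARD_ALL:
                removed.append((t.id, REASON_MONOEXONIC))
                continue
            if mode is MonoexonicMode.ANTISENSE_ONLY and not _overlaps_exon(
                trees, t, _OPPOSITE[t.strand]
            ):
                removed.append((t.id, REASON_MONOEXONIC))
                continue
        if _overlaps_exon(trees, t, t.strand):
            removed.append((t.id, REASON_SENSE_OVERLAP))
            continue
        kept.append(t)
    return kept, removed


def flag_coding_by_homology(
    candidate_ids: Iterable[str],
    hits: Sequence[AlignmentHit],
    cfg: PipelineConfig | None = None,
) -> set[str]:
    """Ids flagged as potential coding by any sufficiently strong protein hit."""
    cfg = cfg or PipelineConfig()
    flagged = set()
    wanted = set(candidate_ids)
    for h in hits:
        if (
            h.query_id in wanted
            and h.pident > cfg.identity_cutoff
            and h.evalue < cfg.evalue_cutoff
        ):
            flagged.add(h.query_id)
    return flagged


def homology_filter(
    candidates: Sequence[GenomicTranscript],
    hits: Sequence[AlignmentHit],
    cfg: PipelineConfig | None = None,
) -> tuple[list[GenomicTranscript], list[GenomicTranscript]]:
    """Split candidates into (kept, flagged_coding) by protein homology."""
    flagged_ids = flag_coding_by_homology((t.id for t in candidates), hits, cfg)
    kept = [t for t in candidates if t.id not in flagged_ids]
    flagged = [t for t in candidates if t.id in flagged_ids]
    return kept, flagged
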