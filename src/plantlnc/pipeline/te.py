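"""Transposable-element origin of identified lncRNAs.

The exons of each lncRNA are intersected, strand-agnostically, with the
union of the annotated TE intervals. A lncRNA is called TE-derived when the
total intersected length reaches the configured minimum (1 bp by default);
the overlap fraction of the exonic length is reported alongside so users
can re-threshold without re-running the intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .models import GenomicTranscript, PipelineConfig


@dataclass(frozen=True)
class TeAnnotation:
    te_overlap_bp: int
    te_fraction: float
    te_families: tuple[str, ...]
    is_te_derived: bool


def _merged(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = out[-1]
        if s <= pe:
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def te_origin(
    lncs: Sequence[GenomicTranscript],
    te_intervals: Sequence[tuple[str, int, int, str]],
    cfg: PipelineConfig | None = None,
) -> dict[str, TeAnnotation]:
    """Per-lncRNA TE overlap: total exonic bp intersecting the TE union, the
    distinct families of intersecting TEs, and the TE-derived flag."""
    cfg = cfg or PipelineConfig()
    merged_by_chrom: dict[str, list[tuple[int, int]]] = {}
    family_trees: dict[str, IntervalTree] = {}
    raw_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, fam in te_intervals:
        if e <= s:
            raise ValueError(f"empty TE interval {chrom}:{s}-{e}")
        raw_by_chrom.setdefault(chrom, []).append((s, e))
        family_trees.setdefault(chrom, IntervalTree()).addi(s, e, fam)
    for chrom, ivs in raw_by_chrom.items():
        merged_by_chrom[chrom] = _merged(ivs)

    out: dict[str, TeAnnotation] = {}
    for t in lncs:
        merged = merged_by_chrom.get(t.chrom, [])
        ftree = family_trees.get(t.chrom)
        overlap = 0
        families: set[str] = set()
        for s, e in t.exons:
            for ms, me in merged:
                if ms >= e:
                    break
                ov = min(e, me) - max(s, ms)
                if ov > 0:
                    overlap += ov
            if ftree is not None:
                families.update(iv.data for iv in ftree.overlap(s, e))
        out[t.id] = TeAnnotation(
            te_overlap_bp=overlap,
            te_fraction=overlap / t.exonic_length,
            te_families=tuple(sorted(families)),
            is_te_derived=overlap >= cfg.te_min_overlap_bp,
        )
    return out
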