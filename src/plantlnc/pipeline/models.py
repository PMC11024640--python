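"""Genomic data model for the annotation pipeline.

Coordinates are 0-based half-open internally; the GTF/GFF readers and
writers convert to and from the 1-based inclusive convention of those
formats, and BED is read as-is (already 0-based half-open).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class GenomicTranscript:
    """A transcript as an exon chain on a genome."""

    id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.id}: at least one exon required")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.id}: empty or inverted exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.id}: exons must be sorted and disjoint")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_monoexonic(self) -> bool:
        return len(self.exons) == 1

    @property
    def tss(self) -> int:
        """Strand-aware 5' end."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Strand-aware 3' end."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class GeneModel:
    """A reference gene: span, strand, and the union of its transcripts."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[GenomicTranscript, ...]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def exons(self) -> tuple[tuple[int, int], ...]:
        out = sorted({ex for t in self.transcripts for ex in t.exons})
        return tuple(out)

    @classmethod
    def from_transcripts(
        cls, gene_id: str, transcripts: Sequence[GenomicTranscript]
    ) -> "GeneModel":
        chroms = {t.chrom for t in transcripts}
        strands = {t.strand for t in transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{gene_id}: transcripts span multiple chroms/strands")
        return cls(
            gene_id,
            chroms.pop(),
            strands.pop(),
            min(t.start for t in transcripts),
            max(t.end for t in transcripts),
            tuple(transcripts),
        )


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column tabular protein alignment (extra columns kept)."""

    query_id: str
    subject_id: str
    pident: float
    evalue: float
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"{self.query_id}: pident out of [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")


class LncClass(enum.Enum):
    """Six-way positional category of an identified lncRNA."""

    INTERGENIC = "INTERGENIC"
    INTRONIC = "INTRONIC"
    ANTISENSE_EXONIC = "ANTISENSE_EXONIC"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    BIDIRECTIONAL = "BIDIRECTIONAL"


class MonoexonicMode(enum.Enum):
    """Fate of monoexonic candidates during filtering.

    ``ANTISENSE_ONLY`` keeps a monoexonic candidate only when one of its
    exons overlaps a reference exon on the opposite strand (the ``monoex =
    -1`` semantics of the established filter).
    """

    KEEP_ALL = "keep_all"
    DISCARD_ALL = "discard_all"
    ANTISENSE_ONLY = "antisense_only"


@dataclass
class PipelineConfig:
    """Thresholds of the identification/characterization stages."""

    min_length_nt: int = 200
    monoex_mode: MonoexonicMode = MonoexonicMode.ANTISENSE_ONLY
    window_bp: int = 2000
    identity_cutoff: float = 80.0  # strict >, percent
    evalue_cutoff: float = 1e-5  # strict <
    te_min_overlap_bp: int = 1
    dedup_identity: float = 0.80

    def __post_init__(self) -> None:
        if isinstance(self.monoex_mode, str):
            self.monoex_mode = MonoexonicMode(self.monoex_mode)
        if self.min_length_nt <= 0 or self.te_min_overlap_bp <= 0:
            raise ValueError("thresholds must be positive")
        if self.window_bp < 0:
            raise ValueError("window must be >= 0")
        if not (0 < self.dedup_identity < 1):
            raise ValueError("dedup identity must be in (0, 1)")


@dataclass
class ClassifiedLncRNA:
    """A lncRNA with its positional class, partner gene and TE annotation."""

    transcript_id: str
    lnc_class: LncClass
    partner_gene_id: str | None
    distance_bp: int
    te_overlap_bp: int = 0
    te_fraction: float = 0.0
    te_families: tuple[str, ...] = field(default_factory=tuple)
    is_te_derived: bool = False

    def __post_init__(self) -> None:
        if (self.partner_gene_id is None) != (self.lnc_class is LncClass.INTERGENIC):
            raise ValueError(
                f"{self.transcript_id}: partner gene present iff class is not INTERGENIC"
            )
        if self.distance_bp < 0:
            raise ValueError(f"{self.transcript_id}: negative distance")
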