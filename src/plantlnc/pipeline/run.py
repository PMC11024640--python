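"""End-to-end lncRNA identification and characterization.

Stages, in order: candidate filtering (length / monoexonic / same-strand
mRNA overlap), ensemble coding-potential prediction with two trained
models, protein-homology filtering, six-way positional classification, and
TE-origin annotation. The stage summary conserves counts: every input
transcript is either kept at the end or appears exactly once in the removal
log.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ..classifiers import TrainedModel, ensemble_classify, extract_for_model, load_model
from ..labels import LNCRNA
from ..seqio import NucleotideSequence, read_fasta, write_fasta
from .filters import filter_candidates, flag_coding_by_homology
from .gxf import read_alignment_hits, read_bed, read_genes, read_transcripts, write_gtf
from .models import ClassifiedLncRNA, GenomicTranscript, PipelineConfig
from .positional import classify_positions
from .te import te_origin

STAGE_FILTER = "candidate_filter"
STAGE_CODING = "coding_potential"
STAGE_HOMOLOGY = "homology_filter"
REASON_CODING = "predicted_coding"
REASON_HOMOLOGY = "protein_homology"


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_kept: int
    n_removed: int


@dataclass
class PipelineResult:
    lncrnas: list[GenomicTranscript]
    classified: list[ClassifiedLncRNA]
    removal_log: list[tuple[str, str, str]]  # (transcript_id, stage, reason)
    stages: list[StageCount]
    scores: dict[str, tuple[float, float]]  # ensemble member scores per candidate

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stage, s.n_in, s.n_kept, s.n_removed) for s in self.stages],
            columns=["stage", "in", "kept", "removed"],
        )

    def classification_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.classified:
            rows.append(
                (
                    c.transcript_id,
                    c.lnc_class.value,
                    c.partner_gene_id or "",
                    c.distance_bp,
                    c.te_overlap_bp,
                    round(c.te_fraction, 6),
                    ",".join(c.te_families),
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "transcript_id",
                "class",
                "partner_gene",
                "distance_bp",
                "te_overlap_bp",
                "te_fraction",
                "te_families",
            ],
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(
    assembled_gtf: str | Path,
    transcript_fasta: str | Path,
    reference_gtf: str | Path,
    model_path: str | Path,
    model2_path: str | Path,
    hits_path: str | Path | None = None,
    te_path: str | Path | None = None,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run all identification/characterization stages and optionally write
    the standard output set (lncRNA.gtf / lncRNA.fa / classification.tsv /
    summary.tsv / removed.tsv) into ``outdir``."""
    cfg = cfg or PipelineConfig()
    candidates = read_transcripts(assembled_gtf)
    genes = read_genes(reference_gtf)
    seqs = {s.id: s for s in read_fasta(transcript_fasta)}
    missing = [t.id for t in candidates if t.id not in seqs]
    if missing:
        raise StageError("input", f"transcripts without sequences: {missing[:5]}")
    model_a = load_model(model_path)
    model_b = load_model(model2_path)

    removal_log: list[tuple[str, str, str]] = []
    stages: list[StageCount] = []

    # stage 1: candidate filter
    kept, removed = filter_candidates(candidates, genes, cfg)
    removal_log.extend((tid, STAGE_FILTER, reason) for tid, reason in removed)
    stages.append(StageCount(STAGE_FILTER, len(candidates), len(kept), len(removed)))

    # stage 2: ensemble coding-potential prediction
    scores: dict[str, tuple[float, float]] = {}
    survivors: list[GenomicTranscript] = []
    for t in kept:
        try:
            fv_a, score_a = extract_for_model(model_a, seqs[t.id])
            fv_b, score_b = extract_for_model(model_b, seqs[t.id])
        except ValueError as e:
            raise StageError(STAGE_CODING, f"{t.id}: {e}") from e
        scores[t.id] = (score_a, score_b)
        if ensemble_classify(model_a, model_b, fv_a, fv_b) == LNCRNA:
            survivors.append(t)
        else:
            removal_log.append((t.id, STAGE_CODING, REASON_CODING))
    stages.append(
        StageCount(STAGE_CODING, len(kept), len(survivors), len(kept) - len(survivors))
    )

    # stage 3: protein homology
    hits = read_alignment_hits(hits_path) if hits_path else []
    flagged = flag_coding_by_homology((t.id for t in survivors), hits, cfg)
    lncrnas = [t for t in survivors if t.id not in flagged]
    removal_log.extend((tid, STAGE_HOMOLOGY, REASON_HOMOLOGY) for tid in sorted(flagged))
    stages.append(StageCount(STAGE_HOMOLOGY, len(survivors), len(lncrnas), len(flagged)))

    # stage 4: positional classification
    classified = classify_positions(lncrnas, genes, cfg)

    # stage 5: TE origin
    te_intervals = read_bed(te_path) if te_path else []
    te = te_origin(lncrnas, te_intervals, cfg)
    for c in classified:
        ann = te[c.transcript_id]
        c.te_overlap_bp = ann.te_overlap_bp
        c.te_fraction = ann.te_fraction
        c.te_families = ann.te_families
        c.is_te_derived = ann.is_te_derived

    result = PipelineResult(lncrnas, classified, removal_log, stages, scores)
    if len(candidates) != len(lncrnas) + len(removal_log):
        raise StageError("conservation", "stage counts do not conserve input transcripts")
    if outdir is not None:
        _write_outputs(result, seqs, Path(outdir))
    return result


def _write_outputs(
    result: PipelineResult, seqs: dict[str, NucleotideSequence], outdir: Path
) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(result.lncrnas, outdir / "lncRNA.gtf")
    write_fasta((seqs[t.id] for t in result.lncrnas), outdir / "lncRNA.fa")
    result.classification_frame().to_csv(outdir / "classification.tsv", sep="\t", index=False)
    result.summary_frame().to_csv(outdir / "summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        result.removal_log, columns=["transcript_id", "stage", "reason"]
    ).to_csv(outdir / "removed.tsv", sep="\t", index=False)
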