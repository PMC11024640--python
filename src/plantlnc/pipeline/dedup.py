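"""Greedy redundancy removal at a pairwise-identity threshold.

Mirrors the incremental clustering convention of CD-HIT-EST: sequences are
visited in order of decreasing length (ties by id), each joins the first
existing representative it exceeds the identity threshold with, otherwise
it founds a new cluster. Pairwise identity is the number of identically
matched columns of the best local alignment (match +1, mismatch -1, gap
open -2, gap extend -1) divided by the length of the *shorter* sequence.
"""

from __future__ import annotations

from typing import Sequence

from Bio import Align

from ..seqio import NucleotideSequence


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(
    a: NucleotideSequence,
    b: NucleotideSequence,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Best-local-alignment identity over the shorter sequence length."""
    aligner = aligner or make_aligner()
    alignments = aligner.align(a.residues, b.residues)
    try:
        best = alignments[0]
    except IndexError:
        return 0.0
    identities = best.counts().identities
    return identities / min(len(a), len(b))


def deduplicate(
    seqs: Sequence[NucleotideSequence],
    identity: float = 0.80,
) -> tuple[list[NucleotideSequence], dict[str, str]]:
    """Greedy clustering; returns representatives and the id -> representative map.

    A sequence joins a cluster only when its identity with the representative
    is strictly greater than the threshold, so a pair at exactly the
    threshold stays separate. Deterministic for a fixed input set.
    """
    if not 0 < identity < 1:
        raise ValueError("identity threshold must be in (0, 1)")
    aligner = make_aligner()
    ordered = sorted(seqs, key=lambda s: (-len(s), s.id))
    reps: list[NucleotideSequence] = []
    assignment: dict[str, str] = {}
    for s in ordered:
        placed = False
        for rep in reps:
            if pairwise_identity(s, rep, aligner) > identity:
                assignment[s.id] = rep.id
                placed = True
                break
        if not placed:
            reps.append(s)
            assignment[s.id] = s.id
    return reps, assignment
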