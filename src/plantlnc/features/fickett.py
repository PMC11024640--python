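"""Fickett TESTCODE statistic.

For each base the statistic combines a *position* value — how unevenly the
base is distributed over the three codon positions, ``max/(min+1)`` of the
three per-position counts — and a *content* value, the base's overall
fraction. Each value is mapped through a published 10-bin lookup table to a
probability of coding, weighted by the base's published weight (a measure of
how informative that base is), and the eight weighted probabilities are
summed. The lookup tables and weights are embedded constants transcribed
from the classic TESTCODE publication as redistributed with coding-potential
tools; position bins step by 0.1 over [1.1, 1.9] and content bins by 0.02
over [0.17, 0.33], each with an open top bin and a catch-all bottom bin.
"""

from __future__ import annotations

from ..seqio import NucleotideSequence

# thresholds are descending; a value v falls in the first bin with v >= threshold
POSITION_BINS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
CONTENT_BINS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, bins: tuple[float, ...], probs: tuple[float, ...]) -> float:
    for threshold, prob in zip(bins, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def position_value(counts: tuple[int, int, int]) -> float:
    return max(counts) / (min(counts) + 1)


def fickett_score(seq: NucleotideSequence | str) -> float:
    """TESTCODE score of a transcript; higher means more coding-like.

    ``N`` residues are ignored for both position and content statistics.
    Raises ``ValueError`` on sequences with fewer than 3 informative
    (non-N) residues.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    pos_counts = {b: [0, 0, 0] for b in "ACGT"}
    total = 0
    for i, c in enumerate(residues):
        if c == "N":
            continue
        pos_counts[c][i % 3] += 1
        total += 1
    if total < 3:
        raise ValueError("Fickett score needs at least 3 non-N residues")
    score = 0.0
    for b in "ACGT":
        c0, c1, c2 = pos_counts[b]
        pv = position_value((c0, c1, c2))
        cv = (c0 + c1 + c2) / total
        score += POSITION_WEIGHT[b] * _lookup(pv, POSITION_BINS, POSITION_PROB[b])
        score += CONTENT_WEIGHT[b] * _lookup(cv, CONTENT_BINS, CONTENT_PROB[b])
    return score
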