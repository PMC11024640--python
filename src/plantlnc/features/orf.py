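"""Open reading frame detection on transcript sequences.

The search is forward-strand only by default: assembled transcripts are
stranded, so coding potential is assessed in the orientation the transcript
was assembled in. An explicit ``reverse=True`` additionally scans the
reverse complement and returns whichever strand carries the longer ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..seqio import NucleotideSequence

# A=0 C=1 G=2 T=3, N=4 (codons containing N are neither start nor stop)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4

_ATG = 0 * 16 + 3 * 4 + 2  # 14
_STOPS = np.array([3 * 16 + 0 + 0, 3 * 16 + 0 + 2, 3 * 16 + 2 * 4 + 0])  # TAA TAG TGA

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class OrfResult:
    """Longest ORF of a transcript, 0-based half-open on the input sequence.

    ``length_nt`` counts the stop codon when ``complete`` is True. An empty
    result (no ATG-initiated ORF) has ``start == end == length_nt == 0``.
    """

    start: int
    end: int
    length_nt: int
    frame: int
    complete: bool

    def __post_init__(self) -> None:
        if self.end - self.start != self.length_nt:
            raise ValueError("ORF length must equal end - start")
        if self.length_nt % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")


def encode(residues: str) -> np.ndarray:
    """Map a validated A/C/G/T/N string to codes 0..4."""
    codes = _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        raise ValueError("sequence contains characters outside A/C/G/T/N")
    return codes


def _codon_values(codes: np.ndarray) -> np.ndarray:
    """Value of the codon starting at each position (-1 if it contains N)."""
    L = codes.size
    if L < 3:
        return np.empty(0, dtype=np.int32)
    c0 = codes[: L - 2].astype(np.int32)
    c1 = codes[1 : L - 1].astype(np.int32)
    c2 = codes[2:].astype(np.int32)
    vals = c0 * 16 + c1 * 4 + c2
    vals[(c0 > 3) | (c1 > 3) | (c2 > 3)] = -1
    return vals


def find_longest_orf(
    seq: NucleotideSequence | str,
    require_stop: bool = True,
    reverse: bool = False,
) -> OrfResult:
    """Locate the longest ATG-initiated in-frame ORF over the three forward frames.

    Ties are broken by smallest start position, then smallest frame. With
    ``require_stop=False`` an ATG that runs to the last full codon of its
    frame without hitting a stop is also eligible (reported incomplete);
    otherwise only stop-terminated ORFs count, and the stop codon is
    included in the reported length.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    best = _scan(residues, require_stop)
    if reverse:
        rc = residues.translate(_RC)[::-1]
        other = _scan(rc, require_stop)
        if other.length_nt > best.length_nt:
            best = other
    return best


def _scan(residues: str, require_stop: bool) -> OrfResult:
    codes = encode(residues)
    vals = _codon_values(codes)
    # candidates: (length, start, frame, end, complete)
    best: tuple[int, int, int, int, bool] | None = None
    for frame in range(3):
        fvals = vals[frame::3]
        if fvals.size == 0:
            continue
        pos = np.arange(fvals.size) * 3 + frame  # nt offset of each codon
        atg_idx = np.flatnonzero(fvals == _ATG)
        if atg_idx.size == 0:
            continue
        stop_idx = np.flatnonzero(np.isin(fvals, _STOPS))
        nxt = np.searchsorted(stop_idx, atg_idx)
        has_stop = nxt < stop_idx.size
        starts = pos[atg_idx]
        ends = np.where(
            has_stop,
            pos[stop_idx[np.minimum(nxt, max(stop_idx.size - 1, 0))]] + 3
            if stop_idx.size
            else 0,
            pos[-1] + 3,
        )
        complete = has_stop
        if require_stop:
            keep = has_stop
            starts, ends, complete = starts[keep], ends[keep], complete[keep]
        if starts.size == 0:
            continue
        lengths = ends - starts
        # longest, then leftmost
        order = np.lexsort((starts, -lengths))
        i = order[0]
        cand = (int(lengths[i]), int(starts[i]), frame, int(ends[i]), bool(complete[i]))
        if best is None or (cand[0], -cand[1], -cand[2]) > (best[0], -best[1], -best[2]):
            best = cand
    if best is None:
        return OrfResult(0, 0, 0, 0, False)
    length, start, frame, end, complete = best
    return OrfResult(start, end, length, frame, complete)


def orf_coverage(orf: OrfResult, seq: NucleotideSequence | str) -> float:
    """Fraction of the transcript covered by its longest ORF."""
    L = len(seq.residues if isinstance(seq, NucleotideSequence) else seq)
    return orf.length_nt / L
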