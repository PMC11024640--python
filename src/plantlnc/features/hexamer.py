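"""Hexamer usage bias: coding/noncoding 6-mer background tables and the
log-likelihood-ratio score built on them.

The coding background is counted over in-frame hexamers (step 3) of each
coding sequence's longest ORF — i.e. adjacent codon pairs — while the
noncoding background is counted over all overlapping hexamers (step 1) of
each noncoding sequence. Counts receive a pseudocount, are normalized to a
probability distribution over all 4096 hexamers, and are stored as natural
logarithms. A transcript's hexamer score is the mean log-ratio
``log f_coding(h) - log f_noncoding(h)`` over its scorable hexamers.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

from ..seqio import NucleotideSequence
from .orf import encode, find_longest_orf

N_HEXAMERS = 4096
HEXAMERS = tuple("".join(p) for p in product("ACGT", repeat=6))

_POWERS = 4 ** np.arange(5, -1, -1)


def hexamer_indices(residues: str, step: int, start: int = 0, end: int | None = None) -> np.ndarray:
    """Indices (0..4095) of the hexamers of ``residues[start:end]`` taken at
    the given step; hexamers containing N are dropped."""
    segment = residues[start:end]
    codes = encode(segment)
    L = codes.size
    if L < 6:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, 6)[::step]
    valid = (windows < 4).all(axis=1)
    return (windows[valid].astype(np.int64) @ _POWERS).astype(np.int64)


def orf_frame_hexamers(seq: NucleotideSequence) -> np.ndarray:
    """Hexamer indices used to score a transcript: in-frame (step 3) over the
    longest ORF when it spans at least one hexamer, otherwise step-1 over the
    whole sequence. Incomplete ORFs are eligible (stop codon not required)."""
    orf = find_longest_orf(seq, require_stop=False)
    if orf.length_nt >= 6:
        return hexamer_indices(seq.residues, 3, orf.start, orf.end)
    return hexamer_indices(seq.residues, 1)


@dataclass(frozen=True)
class HexamerTable:
    """Log-frequency tables over all 4096 hexamers, coding vs noncoding."""

    coding_logfreq: np.ndarray
    noncoding_logfreq: np.ndarray
    pseudocount: float
    n_coding_hexamers: int
    n_noncoding_hexamers: int

    def __post_init__(self) -> None:
        for arr in (self.coding_logfreq, self.noncoding_logfreq):
            if arr.shape != (N_HEXAMERS,):
                raise ValueError("hexamer tables must have 4096 entries")
            if not np.all(np.isfinite(arr)):
                raise ValueError("hexamer log-frequencies must be finite")
            if abs(np.exp(arr).sum() - 1.0) > 1e-9:
                raise ValueError("hexamer frequencies must sum to 1")

    @property
    def log_ratio(self) -> np.ndarray:
        return self.coding_logfreq - self.noncoding_logfreq

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("hexamer\tcoding_logfreq\tnoncoding_logfreq\n")
            for i, h in enumerate(HEXAMERS):
                fh.write(
                    f"{h}\t{float(self.coding_logfreq[i])!r}\t{float(self.noncoding_logfreq[i])!r}\n"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HexamerTable":
        coding = np.empty(N_HEXAMERS)
        noncoding = np.empty(N_HEXAMERS)
        lookup = {h: i for i, h in enumerate(HEXAMERS)}
        seen = 0
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("hexamer"):
                raise ValueError(f"{path}: missing hexamer table header")
            for line in fh:
                h, c, nc = line.rstrip("\n").split("\t")
                coding[lookup[h]] = float(c)
                noncoding[lookup[h]] = float(nc)
                seen += 1
        if seen != N_HEXAMERS:
            raise ValueError(f"{path}: expected 4096 hexamer rows, found {seen}")
        # the TSV stores only the log-frequencies; counts are not recoverable
        return cls(coding, noncoding, 1.0, 0, 0)


def _normalized_logfreq(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    smoothed = counts + pseudocount
    return np.log(smoothed / smoothed.sum())


def build_hexamer_table(
    coding: Sequence[NucleotideSequence],
    noncoding: Sequence[NucleotideSequence],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Count hexamer backgrounds from labeled training sequences.

    A coding sequence without an ORF spanning a hexamer is counted in-frame
    (step 3, frame 0) over its whole length instead — the convention of
    tools trained directly on CDS input. Sequences shorter than 6 nt
    contribute nothing. Raises ``ValueError`` on an empty input list or
    non-positive pseudocount.
    """
    if not coding or not noncoding:
        raise ValueError("coding and noncoding training sets must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    coding_counts = np.zeros(N_HEXAMERS)
    n_cod = 0
    for seq in coding:
        orf = find_longest_orf(seq, require_stop=False)
        if orf.length_nt >= 6:
            idx = hexamer_indices(seq.residues, 3, orf.start, orf.end)
        else:
            idx = hexamer_indices(seq.residues, 3)
        coding_counts += np.bincount(idx, minlength=N_HEXAMERS)
        n_cod += idx.size
    noncoding_counts = np.zeros(N_HEXAMERS)
    n_non = 0
    for seq in noncoding:
        idx = hexamer_indices(seq.residues, 1)
        noncoding_counts += np.bincount(idx, minlength=N_HEXAMERS)
        n_non += idx.size
    return HexamerTable(
        coding_logfreq=_normalized_logfreq(coding_counts, pseudocount),
        noncoding_logfreq=_normalized_logfreq(noncoding_counts, pseudocount),
        pseudocount=pseudocount,
        n_coding_hexamers=n_cod,
        n_noncoding_hexamers=n_non,
    )


def hexamer_score(seq: NucleotideSequence, table: HexamerTable) -> float:
    """Mean coding/noncoding log-frequency ratio over the transcript's
    scorable hexamers; 0.0 when no hexamer is scorable."""
    idx = orf_frame_hexamers(seq)
    if idx.size == 0:
        return 0.0
    return float(table.log_ratio[idx].mean())
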