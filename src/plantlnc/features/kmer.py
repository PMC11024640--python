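"""Scale-weighted k-mer frequency profiles (PLEK-style feature schema).

For every k in ``[k_min, k_max]`` the profile holds the frequency of each of
the 4^k k-mers, counted with step 1 and divided by the number of valid
windows, then multiplied by the per-k weight ``w_k = 1 / 4^(k_max - k)``.
The weight upweights longer, sparser k-mers so that all scales contribute
comparably to a downstream margin-based classifier. k-mers containing N are
excluded from both the counts and the denominator.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from ..seqio import NucleotideSequence
from .orf import encode

DEFAULT_K_MIN = 1
DEFAULT_K_MAX = 5


def kmer_names(k_min: int = DEFAULT_K_MIN, k_max: int = DEFAULT_K_MAX) -> tuple[str, ...]:
    names: list[str] = []
    for k in range(k_min, k_max + 1):
        names.extend("".join(p) for p in product("ACGT", repeat=k))
    return tuple(names)


def kmer_weight(k: int, k_max: int) -> float:
    return 1.0 / 4 ** (k_max - k)


def kmer_profile(
    seq: NucleotideSequence | str,
    k_min: int = DEFAULT_K_MIN,
    k_max: int = DEFAULT_K_MAX,
) -> np.ndarray:
    """Concatenated weighted k-mer frequencies for k = k_min..k_max.

    With the defaults (k 1..5) the vector has 4+16+64+256+1024 = 1364
    entries, ordered lexicographically within each k.
    """
    if not (1 <= k_min <= k_max <= 6):
        raise ValueError("require 1 <= k_min <= k_max <= 6")
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if len(residues) < k_max:
        raise ValueError(f"sequence shorter than k_max={k_max}")
    codes = encode(residues)
    parts: list[np.ndarray] = []
    for k in range(k_min, k_max + 1):
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = (windows < 4).all(axis=1)
        powers = 4 ** np.arange(k - 1, -1, -1)
        idx = windows[valid].astype(np.int64) @ powers
        counts = np.bincount(idx, minlength=4**k).astype(float)
        n_windows = int(valid.sum())
        freqs = counts / n_windows if n_windows else counts
        parts.append(freqs * kmer_weight(k, k_max))
    return np.concatenate(parts)
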