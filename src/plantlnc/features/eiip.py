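"""Electron-ion interaction pseudopotential (EIIP) spectrum features.

Coding sequence carries a characteristic period-3 signal: mapping residues
to their EIIP values and taking the discrete Fourier power spectrum yields
a peak at frequency L/3 for codon-structured sequence. The features exposed
here are the raw period-3 power, its signal-to-noise ratio against the mean
power over all nonzero frequencies, and three quantiles of the normalized
spectrum (which summarize how concentrated the spectral energy is).
"""

from __future__ import annotations

import numpy as np

from ..seqio import NucleotideSequence

EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}
EIIP["N"] = sum(EIIP[b] for b in "ACGT") / 4.0

EIIP_FEATURE_NAMES = (
    "eiip_period3_power",
    "eiip_snr",
    "eiip_spectrum_q25",
    "eiip_spectrum_q50",
    "eiip_spectrum_q75",
)

MIN_LENGTH = 12


def eiip_spectrum_features(seq: NucleotideSequence | str) -> dict[str, float]:
    """Period-3 power, SNR, and spectrum quantiles of the EIIP series.

    Requires at least 12 nt. A spectrally flat input (homopolymer) has zero
    power at every nonzero frequency; its SNR and quantiles are defined as 0.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    L = len(residues)
    if L < MIN_LENGTH:
        raise ValueError(f"EIIP features need at least {MIN_LENGTH} nt, got {L}")
    series = np.array([EIIP[c] for c in residues])
    spectrum = np.abs(np.fft.rfft(series)) ** 2
    power = spectrum[1:]  # nonzero frequencies only; DC carries no signal
    p3_index = min(round(L / 3), L // 2)
    p3_power = float(spectrum[p3_index])
    mean_power = float(power.mean())
    snr = p3_power / mean_power if mean_power > 0 else 0.0
    total = power.sum()
    normalized = power / total if total > 0 else power
    q25, q50, q75 = np.quantile(normalized, (0.25, 0.50, 0.75))
    return {
        "eiip_period3_power": p3_power,
        "eiip_snr": snr,
        "eiip_spectrum_q25": float(q25),
        "eiip_spectrum_q50": float(q50),
        "eiip_spectrum_q75": float(q75),
    }
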