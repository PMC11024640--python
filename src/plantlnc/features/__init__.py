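"""Feature schemas for coding-potential classification.

Three schemas are supported, mirroring the feature families of the
established coding-potential tools:

``cpat``
    Four features: maximum ORF length (nt), ORF coverage, Fickett TESTCODE
    score, and hexamer usage bias (needs a trained :class:`HexamerTable`).
``plek``
    The 1364-dimensional scale-weighted k-mer frequency profile (k = 1..5).
``lncfinder-lite``
    ORF length/coverage, the coding and noncoding mean hexamer
    log-frequencies over the ORF plus their difference, GC fraction, and
    five EIIP power-spectrum features. This is an explicit stand-in for the
    full LncFinder feature set: the secondary-structure block, which would
    require an RNA folding engine, is replaced by the physicochemical EIIP
    subset, and :func:`extract_features` accepts externally computed extra
    features through the ``extra`` hook.

Throughout, ORFs are searched with ``require_stop=False`` (an ORF running
off the 3' end still counts), which is the convention coding-potential
tools use for truncated assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..seqio import NucleotideSequence
from .eiip import EIIP_FEATURE_NAMES, eiip_spectrum_features
from .fickett import fickett_score
from .hexamer import (
    HexamerTable,
    build_hexamer_table,
    hexamer_score,
    orf_frame_hexamers,
)
from .kmer import DEFAULT_K_MAX, DEFAULT_K_MIN, kmer_names, kmer_profile
from .orf import OrfResult, find_longest_orf, orf_coverage

__all__ = [
    "FeatureVector",
    "HexamerTable",
    "OrfResult",
    "SCHEMAS",
    "CachedExtractor",
    "build_hexamer_table",
    "extract_features",
    "feature_matrix",
    "fickett_score",
    "find_longest_orf",
    "hexamer_score",
    "kmer_profile",
    "eiip_spectrum_features",
    "orf_coverage",
    "schema_feature_names",
]

CPAT_FEATURES = ("orf_length_nt", "orf_coverage", "fickett_score", "hexamer_score")
LNCFINDER_LITE_FEATURES = (
    "orf_length_nt",
    "orf_coverage",
    "orf_coding_logfreq_mean",
    "orf_noncoding_logfreq_mean",
    "hexamer_score",
    "gc_fraction",
) + EIIP_FEATURE_NAMES

SCHEMAS = ("cpat", "plek", "lncfinder-lite")
_NEEDS_TABLE = {"cpat": True, "plek": False, "lncfinder-lite": True}


def schema_feature_names(schema_id: str) -> tuple[str, ...]:
    if schema_id == "cpat":
        return CPAT_FEATURES
    if schema_id == "plek":
        return kmer_names(DEFAULT_K_MIN, DEFAULT_K_MAX)
    if schema_id == "lncfinder-lite":
        return LNCFINDER_LITE_FEATURES
    raise ValueError(f"unknown feature schema {schema_id!r}; expected one of {SCHEMAS}")


@dataclass(frozen=True)
class FeatureVector:
    """An ordered, schema-tagged numeric representation of one transcript."""

    schema_id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != self.values.shape[0]:
            raise ValueError("feature names and values must align")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _orf_hexamer_means(seq: NucleotideSequence, table: HexamerTable) -> tuple[float, float]:
    idx = orf_frame_hexamers(seq)
    if idx.size == 0:
        return 0.0, 0.0
    return float(table.coding_logfreq[idx].mean()), float(
        table.noncoding_logfreq[idx].mean()
    )


def extract_features(
    seq: NucleotideSequence,
    schema_id: str,
    table: HexamerTable | None = None,
    extra: Mapping[str, float] | None = None,
) -> FeatureVector:
    """Compute the feature vector of one transcript under a named schema.

    ``extra`` appends externally computed named features (e.g. structure
    features from a folding engine) after the schema's own block; the
    resulting vector is tagged with the same schema id.
    """
    names = schema_feature_names(schema_id)
    if _NEEDS_TABLE[schema_id] and table is None:
        raise ValueError(f"schema {schema_id!r} requires a hexamer table")
    if schema_id == "plek":
        values = kmer_profile(seq)
    elif schema_id == "cpat":
        orf = find_longest_orf(seq, require_stop=False)
        values = np.array(
            [
                float(orf.length_nt),
                orf_coverage(orf, seq),
                fickett_score(seq),
                hexamer_score(seq, table),
            ]
        )
    else:  # lncfinder-lite
        orf = find_longest_orf(seq, require_stop=False)
        cod_mean, non_mean = _orf_hexamer_means(seq, table)
        e = eiip_spectrum_features(seq)
        values = np.array(
            [
                float(orf.length_nt),
                orf_coverage(orf, seq),
                cod_mean,
                non_mean,
                cod_mean - non_mean,
                seq.gc_fraction,
            ]
            + [e[k] for k in EIIP_FEATURE_NAMES]
        )
    if extra:
        names = names + tuple(extra.keys())
        values = np.concatenate([values, np.fromiter(extra.values(), dtype=float)])
    return FeatureVector(schema_id, names, values)


class CachedExtractor:
    """Feature extraction with the hexamer-table-dependent block factored out.

    Cross-validation rebuilds the hexamer table for every training fold; the
    ORF, Fickett, k-mer and spectrum blocks of each sequence do not change
    between folds, so they are computed once here and only the hexamer
    log-frequency means are recomputed per table.
    """

    def __init__(self, seqs: Sequence[NucleotideSequence], schema_id: str):
        self.schema_id = schema_id
        self.names = schema_feature_names(schema_id)
        self.ids = [s.id for s in seqs]
        n = len(seqs)
        if schema_id == "plek":
            self._static = np.vstack([kmer_profile(s) for s in seqs]) if n else np.empty((0, len(self.names)))
            self._hex_idx = None
        else:
            self._hex_idx = [orf_frame_hexamers(s) for s in seqs]
            rows = []
            for s in seqs:
                orf = find_longest_orf(s, require_stop=False)
                if schema_id == "cpat":
                    rows.append([float(orf.length_nt), orf_coverage(orf, s), fickett_score(s)])
                else:
                    e = eiip_spectrum_features(s)
                    rows.append(
                        [float(orf.length_nt), orf_coverage(orf, s), s.gc_fraction]
                        + [e[k] for k in EIIP_FEATURE_NAMES]
                    )
            self._static = np.array(rows) if n else np.empty((0, 3))

    def matrix(self, table: HexamerTable | None = None) -> np.ndarray:
        """Full feature matrix under the given hexamer table (row per sequence)."""
        if self.schema_id == "plek":
            return self._static
        if table is None:
            raise ValueError(f"schema {self.schema_id!r} requires a hexamer table")
        cod = np.zeros(len(self._hex_idx))
        non = np.zeros(len(self._hex_idx))
        for i, idx in enumerate(self._hex_idx):
            if idx.size:
                cod[i] = table.coding_logfreq[idx].mean()
                non[i] = table.noncoding_logfreq[idx].mean()
        if self.schema_id == "cpat":
            return np.column_stack([self._static, cod - non])
        static = self._static
        return np.column_stack(
            [static[:, :2], cod, non, cod - non, static[:, 2:]]
        )


def feature_matrix(
    seqs: Sequence[NucleotideSequence],
    schema_id: str,
    table: HexamerTable | None = None,
) -> pd.DataFrame:
    """Feature table for a set of transcripts, indexed by transcript id."""
    ex = CachedExtractor(seqs, schema_id)
    mat = ex.matrix(table) if _NEEDS_TABLE[schema_id] else ex.matrix()
    return pd.DataFrame(mat, index=pd.Index(ex.ids, name="transcript_id"), columns=list(ex.names))
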