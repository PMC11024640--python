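"""Candidate filtering and homology filtering rules."""

import numpy as np
import pytest

from plantlnc.pipeline import (
    AlignmentHit,
    GeneModel,
    GenomicTranscript,
    MonoexonicMode,
    PipelineConfig,
    filter_candidates,
    flag_coding_by_homology,
    homology_filter,
)


def tx(id, exons, strand="+", chrom="chr1"):
    return GenomicTranscript(id, chrom, strand, tuple(exons))


def gene(id, exons, strand="+", chrom="chr1"):
    return GeneModel.from_transcripts(id, [tx(f"{id}.t1", exons, strand, chrom)])


REF = [gene("g1", [(1000, 1400), (1900, 2200)], "+")]


def test_length_boundary():
    # exonic length is what counts: 99+100 = 199 < 200 <= 100+100
    kept, removed = filter_candidates(
        [tx("short", [(0, 99), (150, 250)]), tx("exact", [(5000, 5100), (5200, 5300)])],
        REF,
    )
    assert removed == [("short", "length")]
    assert [t.id for t in kept] == ["exact"]


def test_multiexonic_sense_overlap_removed():
    t = tx("s", [(1300, 1500), (1800, 2000)], "+")
    kept, removed = filter_candidates([t], REF)
    assert removed == [("s", "sense_overlap")]


def test_antisense_exon_overlap_is_not_removal_cause():
    t = tx("a", [(1300, 1500), (1800, 2000)], "-")
    kept, removed = filter_candidates([t], REF)
    assert [t.id for t in kept] == ["a"]


def test_monoexonic_modes():
    anti = tx("anti", [(1200, 1600)], "-")
    inter = tx("inter", [(9000, 9400)], "+")
    for mode, expect_kept in [
        (MonoexonicMode.ANTISENSE_ONLY, {"anti"}),
        (MonoexonicMode.KEEP_ALL, {"anti", "inter"}),
        (MonoexonicMode.DISCARD_ALL, set()),
    ]:
        cfg = PipelineConfig(monoex_mode=mode)
        kept, removed = filter_candidates([anti, inter], REF, cfg)
        assert {t.id for t in kept} == expect_kept


def test_monoexonic_sense_overlap_gets_monoexonic_reason_first():
    # monoexonic AND sense-overlapping: removal reason follows rule order
    t = tx("m", [(1300, 1600)], "+")
    _, removed = filter_candidates([t], REF)
    assert removed == [("m", "monoexonic")]


def test_unknown_chromosome_warns_and_keeps_context_free():
    t = tx("c2", [(0, 300), (400, 700)], "+", chrom="chr9")
    with pytest.warns(UserWarning):
        kept, removed = filter_candidates([t], REF)
    assert [t.id for t in kept] == ["c2"]


def test_homology_threshold_strictness():
    cfg = PipelineConfig()
    cands = [tx(i, [(0, 300), (400, 700)]) for i in ("q1", "q2", "q3", "q4")]
    hits = [
        AlignmentHit("q1", "p", 85.0, 1e-10),  # flagged
        AlignmentHit("q2", "p", 80.0, 1e-10),  # identity not > 80
        AlignmentHit("q3", "p", 90.0, 1e-5),  # e-value not < 1e-5
    ]
    kept, flagged = homology_filter(cands, hits, cfg)
    assert [t.id for t in flagged] == ["q1"]
    assert [t.id for t in kept] == ["q2", "q3", "q4"]


def test_homology_flags_match_brute_force_any_oracle():
    rng = np.random.default_rng(17)
    cfg = PipelineConfig()
    ids = [f"q{i}" for i in range(50)]
    for _ in range(50):
        hits = [
            AlignmentHit(
                ids[int(rng.integers(50))], "p",
                float(rng.uniform(50, 100)), float(10.0 ** rng.uniform(-20, 0)),
            )
            for _ in range(int(rng.integers(0, 200)))
        ]
        flagged = flag_coding_by_homology(ids, hits, cfg)
        expected = {
            q for q in ids
            if any(h.query_id == q and h.pident > 80 and h.evalue < 1e-5 for h in hits)
        }
        assert flagged == expected


def test_homology_filter_is_monotone_in_cutoffs():
    rng = np.random.default_rng(23)
    ids = [f"q{i}" for i in range(30)]
    hits = [
        AlignmentHit(ids[int(rng.integers(30))], "p",
                     float(rng.uniform(60, 100)), float(10.0 ** rng.uniform(-12, 0)))
        for _ in range(300)
    ]
    base = flag_coding_by_homology(ids, hits, PipelineConfig())
    stricter_id = flag_coding_by_homology(ids, hits, PipelineConfig(identity_cutoff=90))
    stricter_ev = flag_coding_by_homology(ids, hits, PipelineConfig(evalue_cutoff=1e-8))
    assert stricter_id <= base and stricter_ev <= base


def test_candidates_without_hits_are_kept():
    cands = [tx("q", [(0, 300), (400, 700)])]
    kept, flagged = homology_filter(cands, [], PipelineConfig())
    assert [t.id for t in kept] == ["q"] and flagged == []
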