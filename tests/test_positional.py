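"""Six-way positional classification rules and their precedence."""

import numpy as np
import pytest

from plantlnc.pipeline import (
    GeneModel,
    GenomicTranscript,
    LncClass,
    PipelineConfig,
    classify_positions,
)


def tx(id, exons, strand="+", chrom="chr1"):
    return GenomicTranscript(id, chrom, strand, tuple(exons))


def gene(id, exons, strand="+", chrom="chr1"):
    return GeneModel.from_transcripts(id, [tx(f"{id}.t1", exons, strand, chrom)])


def classify_one(t, genes, cfg=None):
    return classify_positions([t], genes, cfg)[0]


PLUS_GENE = gene("g", [(1000, 1400), (1700, 2000)], "+")


def test_downstream_by_construction():
    c = classify_one(tx("l", [(2500, 3000)], "+"), [PLUS_GENE])
    assert (c.lnc_class, c.partner_gene_id, c.distance_bp) == (LncClass.DOWNSTREAM, "g", 500)


def test_antisense_exonic():
    c = classify_one(tx("l", [(1300, 1500)], "-"), [PLUS_GENE])
    assert (c.lnc_class, c.distance_bp) == (LncClass.ANTISENSE_EXONIC, 0)


def test_intronic_either_strand():
    for strand in "+-":
        c = classify_one(tx("l", [(1450, 1650)], strand), [PLUS_GENE])
        assert c.lnc_class == LncClass.INTRONIC and c.partner_gene_id == "g"


def test_upstream_same_strand():
    c = classify_one(tx("l", [(300, 800)], "+"), [PLUS_GENE])
    assert (c.lnc_class, c.distance_bp) == (LncClass.UPSTREAM, 200)


def test_bidirectional_beats_upstream():
    # divergent orientation within the window classifies as bidirectional
    c = classify_one(tx("l", [(300, 800)], "-"), [PLUS_GENE])
    assert (c.lnc_class, c.distance_bp) == (LncClass.BIDIRECTIONAL, 200)


def test_minus_strand_gene_geometry():
    g = gene("m", [(5000, 5400), (5700, 6000)], "-")
    up = classify_one(tx("l", [(6300, 6800)], "-"), [g])
    assert (up.lnc_class, up.distance_bp) == (LncClass.UPSTREAM, 300)
    bid = classify_one(tx("l", [(6300, 6800)], "+"), [g])
    assert (bid.lnc_class, bid.distance_bp) == (LncClass.BIDIRECTIONAL, 300)
    down = classify_one(tx("l", [(4200, 4600)], "-"), [g])
    assert (down.lnc_class, down.distance_bp) == (LncClass.DOWNSTREAM, 400)


def test_outside_window_is_intergenic():
    c = classify_one(tx("l", [(4001, 4500)], "+"), [PLUS_GENE])
    assert c.lnc_class == LncClass.INTERGENIC and c.partner_gene_id is None


def test_window_boundary_inclusive():
    c = classify_one(tx("l", [(2000 + 2000, 4600)], "+"), [PLUS_GENE])
    assert c.lnc_class == LncClass.DOWNSTREAM and c.distance_bp == 2000


def test_zero_genes_all_intergenic():
    out = classify_positions([tx("a", [(0, 300)]), tx("b", [(900, 1300)], "-")], [])
    assert all(c.lnc_class == LncClass.INTERGENIC for c in out)


def test_partner_tie_broken_by_distance_then_gene_id():
    g1 = gene("ga", [(5000, 5600)], "+")
    g2 = gene("gb", [(5000, 5600)], "+")  # identical span: lexicographic tie-break
    c = classify_one(tx("l", [(4000, 4500)], "+"), [g1, g2])
    assert c.partner_gene_id == "ga"
    g3 = gene("gc", [(4800, 5400)], "+")  # closer TSS wins over id order
    c = classify_one(tx("l", [(4000, 4500)], "+"), [g1, g3])
    assert c.partner_gene_id == "gc" and c.distance_bp == 300


def test_precedence_antisense_over_intronic():
    # lncRNA overlapping exons of an opposite-strand gene while inside
    # another gene's intron: rule 1 wins
    host = gene("host", [(100, 200), (3000, 3200)], "+")
    anti = gene("anti", [(1000, 1200)], "-")
    c = classify_one(tx("l", [(1100, 1400)], "+"), [host, anti])
    assert c.lnc_class == LncClass.ANTISENSE_EXONIC and c.partner_gene_id == "anti"


def test_classes_partition_random_layouts():
    rng = np.random.default_rng(99)
    genes = []
    pos = 1000
    for i in range(15):
        width = int(rng.integers(500, 3000))
        strand = "+" if rng.integers(2) else "-"
        genes.append(gene(f"g{i}", [(pos, pos + width)], strand))
        pos += width + int(rng.integers(100, 6000))
    lncs = []
    for i in range(200):
        start = int(rng.integers(0, pos))
        strand = "+" if rng.integers(2) else "-"
        lncs.append(tx(f"l{i}", [(start, start + int(rng.integers(200, 1500)))], strand))
    out = classify_positions(lncs, genes)
    assert len(out) == len(lncs)
    assert {c.transcript_id for c in out} == {t.id for t in lncs}
    for c in out:
        assert (c.partner_gene_id is None) == (c.lnc_class is LncClass.INTERGENIC)


def test_planted_genome_classes_recovered(genome_sim):
    truth = genome_sim.truth
    kept_ids = set(truth[truth.fate == "kept"].record_id)
    lncs = [t for t in genome_sim.candidates if t.id in kept_ids]
    out = {c.transcript_id: c for c in classify_positions(lncs, genome_sim.reference)}
    for _, row in truth[truth.fate == "kept"].iterrows():
        assert out[row.record_id].lnc_class.value == row.lnc_class, row.record_id
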