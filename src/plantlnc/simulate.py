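"""Seeded synthetic data with the statistical structure the classifiers and
pipeline assume.

Three generators are provided. ``simulate_mrna`` emulates protein-coding
transcripts: a GC-matched 5'UTR, an ORF whose codons are drawn from a
skewed codon-usage distribution (this is what creates a learnable hexamer
signal, not the labels alone), and a 3'UTR, with ORF coverage uniform in
[0.5, 0.9]. ``simulate_lncrna`` emulates long noncoding transcripts:
GC-matched random sequence constrained to carry no ORF of 120 nt or more.
``simulate_genome`` lays out a toy genome with reference genes and planted
lncRNA loci satisfying the defining geometry of each positional class,
plus decoy candidates exercising every removal rule of the pipeline, and
records every planted record's intended fate in a truth table.

All generators are pure functions of their configuration (seed included):
the same config yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .features.orf import find_longest_orf
from .pipeline.gxf import write_gtf
from .pipeline.models import GeneModel, GenomicTranscript
from .seqio import NucleotideSequence, write_fasta

TRUTH_SCHEMA_VERSION = "plantlnc-truth-1"

STOP_CODONS = ("TAA", "TAG", "TGA")
ALL_CODONS = tuple("".join(p) for p in product("ACGT", repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_RC)[::-1]


def default_codon_bias(seed: int = 0) -> dict[str, float]:
    """Skewed codon usage: a fixed 20-codon subset is 8x preferred.

    The subset is drawn deterministically (own fixed stream, independent of
    the simulation seed) so that the default bias is one stable choice, not
    a per-run random one.
    """
    rng = np.random.default_rng(20240301 + seed)
    preferred = rng.choice(len(SENSE_CODONS), size=20, replace=False)
    weights = {c: 1.0 for c in SENSE_CODONS}
    for i in preferred:
        weights[SENSE_CODONS[i]] = 8.0
    return weights


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    ``length_range`` applies to both transcript classes so length itself is
    not a trivial giveaway; its minimum must stay >= 200 nt so the pipeline
    length filter is exercised only by explicitly planted short decoys.
    """

    seed: int = 0
    n_mrna: int = 1000
    n_lnc: int = 1000
    length_range: tuple[int, int] = (400, 3000)
    gc: float = 0.45
    codon_bias: dict[str, float] = field(default_factory=default_codon_bias)
    max_lnc_orf_nt: int = 120
    orf_coverage_range: tuple[float, float] = (0.5, 0.9)
    # genome plan
    loci_per_class: int = 1
    intergenic_gap: tuple[int, int] = (5000, 8000)
    te_overlap_bp: int = 80

    def __post_init__(self) -> None:
        if self.n_mrna < 0 or self.n_lnc < 0 or self.loci_per_class < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.length_range
        if lo < 200 or hi < lo:
            raise ValueError("length_range minimum must be >= 200 nt")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")
        if any(w <= 0 for w in self.codon_bias.values()):
            raise ValueError("codon weights must be positive")
        if self.max_lnc_orf_nt < 30:
            raise ValueError("max_lnc_orf_nt unreasonably small")


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _mrna_sequence(rng: np.random.Generator, length: int, cfg: SimulationConfig) -> str:
    """5'UTR + codon-biased ORF + 3'UTR with ORF coverage in the configured range."""
    cov = rng.uniform(*cfg.orf_coverage_range)
    n_codons = max(3, round(cov * length / 3))
    orf_nt = 3 * n_codons
    if orf_nt > length:
        n_codons = length // 3
        orf_nt = 3 * n_codons
    codons = list(cfg.codon_bias.keys())
    w = np.fromiter(cfg.codon_bias.values(), dtype=float)
    w = w / w.sum()
    interior = rng.choice(len(codons), size=n_codons - 2, p=w)
    orf = "ATG" + "".join(codons[i] for i in interior) + STOP_CODONS[rng.integers(3)]
    utr5 = int(rng.integers(0, length - orf_nt + 1))
    return (
        _random_seq(rng, utr5, cfg.gc)
        + orf
        + _random_seq(rng, length - orf_nt - utr5, cfg.gc)
    )


def _disrupt_orfs(rng: np.random.Generator, seq: str, max_orf_nt: int) -> str:
    """Replace an in-frame codon of each over-long ORF with a stop until no
    ORF reaches ``max_orf_nt``.

    The codon is chosen at random within the ORF: overlapping ORFs in
    different frames can otherwise undo each other's stop insertion
    indefinitely when the position is deterministic.
    """
    for _ in range(500):
        orf = find_longest_orf(seq, require_stop=False)
        if orf.length_nt < max_orf_nt:
            return seq
        n_codons = orf.length_nt // 3
        pos = orf.start + 3 * int(rng.integers(0, n_codons))
        stop = STOP_CODONS[rng.integers(3)]
        seq = seq[:pos] + stop + seq[pos + 3 :]
    raise RuntimeError("failed to suppress ORFs; increase max_lnc_orf_nt")


def _lnc_sequence(
    rng: np.random.Generator, length: int, cfg: SimulationConfig, tries: int = 10
) -> str:
    """GC-matched sequence with longest ORF < max_lnc_orf_nt.

    Plain rejection is attempted first; sequences that keep failing (long
    transcripts almost always contain a >=120 nt ORF by chance) have their
    remaining long ORFs disrupted by in-frame stop substitution.
    """
    for _ in range(tries):
        seq = _random_seq(rng, length, cfg.gc)
        if find_longest_orf(seq, require_stop=False).length_nt < cfg.max_lnc_orf_nt:
            return seq
    return _disrupt_orfs(rng, seq, cfg.max_lnc_orf_nt)


def _truth_frame(seqs: list[NucleotideSequence], label: str) -> pd.DataFrame:
    rows = []
    for s in seqs:
        orf = find_longest_orf(s, require_stop=False)
        rows.append((s.id, label, len(s), round(s.gc_fraction, 4), orf.length_nt))
    return pd.DataFrame(rows, columns=["id", "label", "length", "gc", "longest_orf_nt"])


def simulate_mrna(cfg: SimulationConfig) -> tuple[list[NucleotideSequence], pd.DataFrame]:
    """mRNA-like negative-set transcripts plus their truth table."""
    rng = np.random.default_rng([cfg.seed, 1])
    lo, hi = cfg.length_range
    seqs = [
        NucleotideSequence(f"mrna_{i:05d}", _mrna_sequence(rng, int(rng.integers(lo, hi + 1)), cfg))
        for i in range(cfg.n_mrna)
    ]
    return seqs, _truth_frame(seqs, "mRNA")


def simulate_lncrna(cfg: SimulationConfig) -> tuple[list[NucleotideSequence], pd.DataFrame]:
    """lncRNA-like positive-set transcripts plus their truth table."""
    rng = np.random.default_rng([cfg.seed, 2])
    lo, hi = cfg.length_range
    seqs = [
        NucleotideSequence(f"lnc_{i:05d}", _lnc_sequence(rng, int(rng.integers(lo, hi + 1)), cfg))
        for i in range(cfg.n_lnc)
    ]
    return seqs, _truth_frame(seqs, "lncRNA")


# ---------------------------------------------------------------------------
# planted-truth genome


@dataclass
class GenomeSim:
    """A toy genome with planted genes, lncRNA loci and decoys."""

    chrom: str
    genome: str
    reference: list[GeneModel]
    candidates: list[GenomicTranscript]
    candidate_seqs: list[NucleotideSequence]
    te_intervals: list[tuple[str, int, int, str]]
    hits: list[tuple[str, str, float, float]]
    truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa, reference.gtf, candidates.gtf/.fa, te.bed,
        hits.tsv and truth.tsv; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "reference": outdir / "reference.gtf",
            "candidates_gtf": outdir / "candidates.gtf",
            "candidates_fa": outdir / "candidates.fa",
            "te": outdir / "te.bed",
            "hits": outdir / "hits.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta([NucleotideSequence(self.chrom, self.genome)], paths["genome"])
        ref_tx = [t for g in self.reference for t in g.transcripts]
        write_gtf(ref_tx, paths["reference"])
        write_gtf(self.candidates, paths["candidates_gtf"])
        write_fasta(self.candidate_seqs, paths["candidates_fa"])
        with open(paths["te"], "w") as fh:
            for chrom, s, e, fam in self.te_intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{fam}\t0\t+\n")
        with open(paths["hits"], "w") as fh:
            for qid, sid, pident, evalue in self.hits:
                fh.write(
                    f"{qid}\t{sid}\t{pident}\t100\t5\t0\t1\t100\t1\t100\t{evalue}\t200.0\n"
                )
        with open(paths["truth"], "w") as fh:
            fh.write(f"# {TRUTH_SCHEMA_VERSION}\n")
            self.truth.to_csv(fh, sep="\t", index=False)
        return paths


def extract_transcript_seq(genome: str, t: GenomicTranscript) -> str:
    spliced = "".join(genome[s:e] for s, e in t.exons)
    return revcomp(spliced) if t.strand == "-" else spliced


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    n = max(1, int(rate * len(seq)))
    positions = rng.choice(len(seq), size=n, replace=False)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


def simulate_genome(cfg: SimulationConfig) -> GenomeSim:
    """Build the planted-truth genome fixture.

    Per replicate (``loci_per_class``) the genome carries one lncRNA locus of
    each positional class next to its own host gene, and — once — a set of
    decoys: a sub-200-nt transcript, a monoexonic intergenic transcript, a
    transcript with same-strand exon overlap of a reference gene, an
    mRNA-like candidate (to be removed by the coding-potential ensemble), a
    candidate with a strong protein hit (removed by the homology filter),
    and a high-identity duplicate of the intergenic lncRNA. The truth table
    lists every candidate with its intended fate.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    chrom = "chr1"
    gene_plants: list[tuple[tuple[tuple[int, int], ...], str, str]] = []
    cand_plants: list[tuple[tuple[tuple[int, int], ...], str, str]] = []
    reference: list[GeneModel] = []
    candidates: list[GenomicTranscript] = []
    te_intervals: list[tuple[str, int, int, str]] = []
    hits: list[tuple[str, str, float, float]] = []
    truth_rows: list[tuple[str, str, str, bool, str]] = []

    cursor = 1000

    def gap() -> None:
        nonlocal cursor
        cursor += int(rng.integers(*cfg.intergenic_gap))

    def shift(exons: list[tuple[int, int]], base: int) -> tuple[tuple[int, int], ...]:
        return tuple((base + s, base + e) for s, e in exons)

    def add_gene(name: str, exons_rel: list[tuple[int, int]], base: int, strand: str = "+") -> GeneModel:
        exons = shift(exons_rel, base)
        tx = GenomicTranscript(f"{name}.t1", chrom, strand, exons, gene_id=name)
        gene = GeneModel.from_transcripts(name, [tx])
        total = tx.exonic_length
        gene_plants.append((exons, strand, _mrna_sequence(rng, total, cfg)))
        reference.append(gene)
        return gene

    def add_candidate(
        name: str,
        exons_rel: list[tuple[int, int]],
        base: int,
        strand: str,
        fate: str,
        lnc_class: str = "",
        te_derived: bool = False,
        duplicate_of: str = "",
        seq: str | None = None,
    ) -> GenomicTranscript:
        exons = shift(exons_rel, base)
        tx = GenomicTranscript(name, chrom, strand, exons)
        total = tx.exonic_length
        if seq is None:
            seq = _lnc_sequence(rng, total, cfg)
        cand_plants.append((exons, strand, seq))
        candidates.append(tx)
        truth_rows.append((name, fate, lnc_class, te_derived, duplicate_of))
        return tx

    host_exons = [(0, 400), (1900, 2200), (3400, 3700)]

    for r in range(cfg.loci_per_class):
        # intergenic lncRNA, TE-derived, plus (replicate 0) a near-duplicate
        gap()
        lnc_inter = add_candidate(
            f"lnc_intergenic_{r}", [(0, 250), (550, 800)], cursor, "+",
            "kept", "INTERGENIC", te_derived=True,
        )
        te_intervals.append(
            (chrom, cursor + 50, cursor + 50 + cfg.te_overlap_bp, "LTR/Copia")
        )
        hits.append((lnc_inter.id, "sp|Q00001|WEAK", 80.0, 1e-10))  # kept: identity not > 80
        cursor += 800
        if r == 0:
            gap()
            dup_seq = _mutate(rng, extract_seq_for(lnc_inter, cand_plants), 0.03)
            add_candidate(
                f"dup_intergenic_{r}", [(0, 250), (550, 800)], cursor, "+",
                "kept", "INTERGENIC", duplicate_of=lnc_inter.id, seq=dup_seq,
            )
            cursor += 800

        # intronic lncRNA inside its host gene's first intron
        gap()
        add_gene(f"gene_intronic_{r}", host_exons, cursor)
        add_candidate(
            f"lnc_intronic_{r}", [(500, 750), (850, 1100)], cursor, "+",
            "kept", "INTRONIC",
        )
        cursor += 3700

        # antisense exonic lncRNA: monoexonic, opposite strand over exon 2
        gap()
        add_gene(f"gene_antisense_{r}", host_exons, cursor)
        add_candidate(
            f"lnc_antisense_{r}", [(1700, 2150)], cursor, "-",
            "kept", "ANTISENSE_EXONIC",
        )
        cursor += 3700

        # upstream lncRNA: same strand, 3' end 500 bp before the gene TSS
        gap()
        up = add_candidate(
            f"lnc_upstream_{r}", [(0, 250), (350, 600)], cursor, "+",
            "kept", "UPSTREAM",
        )
        hits.append((up.id, "sp|Q00002|WEAK", 90.0, 1e-3))  # kept: e-value not < 1e-5
        add_gene(f"gene_upstream_{r}", host_exons, cursor + 1100)
        cursor += 1100 + 3700

        # downstream lncRNA: same strand, 5' end 600 bp past the gene TTS
        gap()
        add_gene(f"gene_downstream_{r}", host_exons, cursor)
        add_candidate(
            f"lnc_downstream_{r}", [(4300, 4550), (4750, 5000)], cursor, "+",
            "kept", "DOWNSTREAM",
        )
        cursor += 5000

        # bidirectional lncRNA: divergent, opposite strand, TSS 300 bp apart
        gap()
        add_candidate(
            f"lnc_bidirectional_{r}", [(0, 250), (350, 600)], cursor, "-",
            "kept", "BIDIRECTIONAL",
        )
        add_gene(f"gene_bidirectional_{r}", host_exons, cursor + 900)
        cursor += 900 + 3700

    # decoys (once)
    gap()
    add_candidate("decoy_short_0", [(0, 150)], cursor, "+", "removed_length")
    add_candidate("decoy_monoex_0", [(1000, 1400)], cursor, "+", "removed_monoexonic")
    add_gene("gene_sense_0", host_exons, cursor + 4000)
    add_candidate(
        "decoy_sense_0", [(1800, 2100), (3200, 3500)], cursor + 4000, "+",
        "removed_sense_overlap",
    )
    cursor += 4000 + 3700
    gap()
    coding_len = 300 + 300
    add_candidate(
        "decoy_coding_0", [(0, 300), (800, 1100)], cursor, "+",
        "removed_coding", seq=_mrna_sequence(rng, coding_len, cfg),
    )
    cursor += 1100
    gap()
    hom = add_candidate(
        "decoy_homology_0", [(0, 250), (700, 950)], cursor, "+", "removed_homology"
    )
    hits.append((hom.id, "sp|P00001|STRONG", 85.0, 1e-10))
    cursor += 950
    gap()
    te_intervals.append((chrom, cursor, cursor + 200, "DNA/MuDR"))
    cursor += 200

    genome_len = cursor + 2000
    genome = np.frombuffer(
        _random_seq(rng, genome_len, cfg.gc).encode("ascii"), dtype="S1"
    ).copy()

    def plant(exons: tuple[tuple[int, int], ...], strand: str, seq: str) -> None:
        payload = revcomp(seq) if strand == "-" else seq
        offset = 0
        for s, e in exons:
            chunk = payload[offset : offset + (e - s)]
            genome[s:e] = np.frombuffer(chunk.encode("ascii"), dtype="S1")
            offset += e - s

    for exons, strand, seq in gene_plants:
        plant(exons, strand, seq)
    for exons, strand, seq in cand_plants:
        plant(exons, strand, seq)
    genome_str = genome.tobytes().decode("ascii")

    candidate_seqs = [
        NucleotideSequence(t.id, extract_transcript_seq(genome_str, t))
        for t in candidates
    ]
    truth = pd.DataFrame(
        truth_rows,
        columns=["record_id", "fate", "lnc_class", "te_derived", "duplicate_of"],
    )
    return GenomeSim(
        chrom, genome_str, reference, candidates, candidate_seqs,
        te_intervals, hits, truth,
    )


def extract_seq_for(
    t: GenomicTranscript, plants: list[tuple[tuple[tuple[int, int], ...], str, str]]
) -> str:
    """The sequence most recently planted for a transcript's exon chain."""
    for exons, strand, seq in reversed(plants):
        if exons == t.exons:
            return seq
    raise KeyError(t.id)
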