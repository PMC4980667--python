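"""Seeded generators for every input the pipeline consumes.

Produces a toy genome and annotation with canonical splice-site flanks,
chimeric alignment records with per-criterion decoys and a truth table,
multi-round selection libraries with planted motif affinity, and circRNA
sequence groups with a planted motif-density offset.  All generators are
byte-deterministic under a fixed seed.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import _kmers
from .circ_call import BackspliceJunction, ChimericRecord
from .errors import ConfigurationError, PlacementError, TruthSpecError
from .models import Annotation, GeneModel
from .selex_motif import LibraryLayout, default_selex_layout

DEFAULT_AFFINITY = {
    "CACA": 1.0,
    "ACAC": 0.85,
    "AACA": 0.75,
    "ACAA": 0.55,
    "CAAC": 0.55,
    "AACC": 0.45,
    "CCAA": 0.40,
    "CACC": 0.40,
    "ACCA": 0.35,
    "CAAA": 0.35,
}

DEFAULT_LIBRARIES = ("HepG2", "PANC1", "PATU")

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 100_000
    gc_fraction: float = 0.5
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (3, 5)
    read_length: int = 100
    overhang_min_sim: int = 12
    rounds: int = 4
    pool_size: int = 100_000
    tag_length: int = 20
    affinity_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AFFINITY))
    stringency_schedule: list[float] = field(default_factory=lambda: [1.0, 1.5, 2.0, 2.5])
    survival_midpoint: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ConfigurationError("gc_fraction must be in [0, 1]")
        if self.n_chrom < 1:
            raise ConfigurationError("n_chrom must be >= 1")
        lo, hi = self.exons_per_gene
        if lo < 1 or lo > hi:
            raise ConfigurationError("exons_per_gene must be a valid range with min >= 1")
        if self.read_length < 2 * 1:
            raise ConfigurationError("read_length too small")
        self.exons_per_gene = (int(lo), int(hi))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "SimConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "exons_per_gene" in data:
            data["exons_per_gene"] = tuple(data["exons_per_gene"])
        return cls(**data)


@dataclass
class TrueJunction:
    chrom: str
    strand: str
    acceptor_pos: int
    donor_pos: int
    counts: dict[str, int]


@dataclass
class TruthTable:
    true_junctions: list[TrueJunction] = field(default_factory=list)
    decoy_records: list[tuple[str, int]] = field(default_factory=list)
    true_selex_motif: str = ""

    def expected_junctions(self) -> list[BackspliceJunction]:
        return sorted(
            (
                BackspliceJunction(t.chrom, t.strand, t.acceptor_pos, t.donor_pos, dict(t.counts))
                for t in self.true_junctions
            ),
            key=lambda j: j.key,
        )

    def write(self, out_dir: str | os.PathLike) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "truth_junctions.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["chrom", "strand", "acceptor", "donor", "library_id", "count"])
            for t in self.true_junctions:
                for lib in sorted(t.counts):
                    w.writerow([t.chrom, t.strand, t.acceptor_pos + 1, t.donor_pos, lib, t.counts[lib]])
        with open(os.path.join(out_dir, "truth_decoys.tsv"), "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["record_id", "violated_criterion"])
            for rid, crit in self.decoy_records:
                w.writerow([rid, crit])
        if self.true_selex_motif:
            with open(os.path.join(out_dir, "truth_selex_motif.txt"), "w") as fh:
                fh.write(self.true_selex_motif + "\n")


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def _random_seq_array(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASE_BYTES, size=n, p=p)


def make_genome(config: SimConfig) -> dict[str, str]:
    """Random i.i.d. genome: ``n_chrom`` uppercase chromosomes of equal length."""
    if config.chrom_length < 1000:
        raise ConfigurationError("chrom_length must be >= 1000")
    rng = config.rng(0)
    genome = {}
    for i in range(config.n_chrom):
        arr = _random_seq_array(rng, config.chrom_length, config.gc_fraction)
        genome[f"chr{i + 1}"] = arr.tobytes().decode("ascii")
    return genome


def make_annotation(
    genome: dict[str, str], config: SimConfig
) -> tuple[Annotation, dict[str, str]]:
    """Place non-overlapping genes and patch splice-site flanks into the genome.

    On the ``+`` strand every exon gets AG immediately upstream and GT
    immediately downstream; on ``-`` the reverse complement arrangement
    (AC upstream, CT downstream) so flanks are GT/AG on the transcribed
    strand.  Returns the gene set and the patched genome.
    """
    rng = config.rng(1)
    chroms = list(genome)
    buffers = {c: bytearray(genome[c], "ascii") for c in chroms}
    cursors = {c: 200 for c in chroms}
    genes: list[GeneModel] = []
    lo, hi = config.exons_per_gene
    for gi in range(config.n_genes):
        n_ex = int(rng.integers(lo, hi + 1))
        exon_lens = rng.integers(60, 301, size=n_ex)
        intron_lens = rng.integers(40, 201, size=max(0, n_ex - 1))
        gap = int(rng.integers(300, 801))
        span = int(exon_lens.sum() + intron_lens.sum())
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lincRNA" if rng.random() < 0.15 else "protein_coding"
        placed = False
        for attempt in range(len(chroms)):
            chrom = chroms[(gi + attempt) % len(chroms)]
            start = cursors[chrom] + gap
            if start + span + 200 <= len(genome[chrom]):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"cannot place gene {gi + 1} of span {span} without overlap"
            )
        exons = []
        pos = start
        for j in range(n_ex):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_ex - 1:
                pos += int(intron_lens[j])
        cursors[chrom] = pos
        buf = buffers[chrom]
        for s, e in exons:
            if strand == "+":
                buf[s - 2 : s] = b"AG"
                buf[e : e + 2] = b"GT"
            else:
                buf[s - 2 : s] = b"AC"
                buf[e : e + 2] = b"CT"
        genes.append(GeneModel(f"GENE{gi + 1:04d}", chrom, strand, biotype, exons))
    patched = {c: buffers[c].decode("ascii") for c in chroms}
    return Annotation(genes), patched


# ---------------------------------------------------------------------------
# Chimeric records
# ---------------------------------------------------------------------------

def make_truth_spec(
    annotation: Annotation,
    config: SimConfig,
    n_junctions: int,
    libraries: Sequence[str] = DEFAULT_LIBRARIES,
    count_range: tuple[int, int] = (5, 60),
    counts: Optional[Sequence[dict[str, int]]] = None,
) -> list[TrueJunction]:
    """Pick exon-boundary junction coordinates with per-library read counts."""
    rng = config.rng(5)
    candidates = _boundary_junctions(annotation, config.read_length)
    if len(candidates) < n_junctions:
        raise TruthSpecError(
            f"annotation offers only {len(candidates)} junction sites, need {n_junctions}"
        )
    idx = rng.choice(len(candidates), size=n_junctions, replace=False)
    out = []
    for rank, i in enumerate(sorted(idx)):
        gene, acc, don = candidates[i]
        if counts is not None:
            libcounts = dict(counts[rank])
        else:
            libcounts = {lib: int(rng.integers(count_range[0], count_range[1] + 1)) for lib in libraries}
        out.append(TrueJunction(gene.chrom, gene.strand, acc, don, libcounts))
    return out


def _boundary_junctions(annotation: Annotation, min_span: int) -> list[tuple[GeneModel, int, int]]:
    out = []
    for gene in annotation.genes:
        for i, (s1, _e1) in enumerate(gene.exons):
            for _s2, e2 in gene.exons[i:]:
                if e2 - s1 >= min_span:
                    out.append((gene, s1, e2))
    return out


def _validate_truth(annotation: Annotation, truth: Sequence[TrueJunction]) -> None:
    for t in truth:
        genes = annotation.genes_at_exon_start(
            t.chrom, t.strand, t.acceptor_pos
        ) & annotation.genes_at_exon_end(t.chrom, t.strand, t.donor_pos)
        if not genes:
            raise TruthSpecError(
                f"junction {t.chrom}:{t.acceptor_pos}-{t.donor_pos}({t.strand}) "
                "is not on exon boundaries of one gene"
            )


def _passing_record(
    rng: np.random.Generator,
    record_id: str,
    library_id: str,
    chrom: str,
    strand: str,
    acc: int,
    don: int,
    config: SimConfig,
    margin: Optional[int] = None,
    split: Optional[int] = None,
) -> ChimericRecord:
    read_len = config.read_length
    min_oh = config.overhang_min_sim
    if split is None:
        split = int(rng.integers(min_oh, read_len - min_oh + 1))
    la, lb = split, read_len - split
    if margin is None:
        margin = int(rng.integers(3, 21))
    score = read_len
    if strand == "+":
        seg_a = (don - la, don)
        seg_b = (acc, acc + lb)
    else:
        seg_a = (acc, acc + la)
        seg_b = (don - lb, don)
    return ChimericRecord(
        record_id=record_id,
        library_id=library_id,
        chrom_a=chrom,
        start_a=seg_a[0],
        end_a=seg_a[1],
        strand_a=strand,
        chrom_b=chrom,
        start_b=seg_b[0],
        end_b=seg_b[1],
        strand_b=strand,
        chimeric_score=score,
        best_linear_score=score - margin,
    )


def simulate_chimeric_records(
    genome: dict[str, str],
    annotation: Annotation,
    truth_spec: Sequence[TrueJunction],
    config: SimConfig,
    decoys_per_class: int = 25,
) -> tuple[list[ChimericRecord], TruthTable]:
    """Generate criterion-passing records per true junction plus labelled decoys.

    Decoy classes: 1 = geometry (opposite strand / forward order /
    trans-chromosome), 2 = short overhang, 3 = insufficient score margin,
    4 = non-annotated non-canonical junction.  Each decoy violates exactly
    its own criterion and satisfies the other three.
    """
    _validate_truth(annotation, truth_spec)
    rng = config.rng(2)
    records: list[ChimericRecord] = []
    truth = TruthTable(true_junctions=list(truth_spec))

    for ji, t in enumerate(truth_spec):
        if t.donor_pos - t.acceptor_pos < config.read_length:
            raise TruthSpecError("true junction span must be >= read_length")
        for lib in sorted(t.counts):
            for n in range(t.counts[lib]):
                records.append(
                    _passing_record(
                        rng, f"true_j{ji}_{lib}_{n}", lib, t.chrom, t.strand,
                        t.acceptor_pos, t.donor_pos, config,
                    )
                )

    decoy_sites = _boundary_junctions(annotation, config.read_length)
    if not decoy_sites:
        raise TruthSpecError("annotation offers no junction sites for decoys")
    libraries = sorted({lib for t in truth_spec for lib in t.counts}) or list(DEFAULT_LIBRARIES)

    def site(i):
        gene, acc, don = decoy_sites[i % len(decoy_sites)]
        return gene, acc, don

    # class 1: geometry violations
    modes = ["strand", "order"] + (["transchrom"] if len(genome) > 1 else [])
    for i in range(decoys_per_class):
        gene, acc, don = site(int(rng.integers(len(decoy_sites))))
        lib = libraries[i % len(libraries)]
        rid = f"decoy1_{i}"
        base = _passing_record(rng, rid, lib, gene.chrom, gene.strand, acc, don, config)
        mode = modes[i % len(modes)]
        if mode == "strand":
            rec = ChimericRecord(
                **{**asdict(base), "strand_b": "-" if gene.strand == "+" else "+"}
            )
        elif mode == "order":
            d = asdict(base)
            rec = ChimericRecord(
                **{
                    **d,
                    "start_a": base.start_b,
                    "end_a": base.end_b,
                    "start_b": base.start_a,
                    "end_b": base.end_a,
                    "overhang_a": base.overhang_b,
                    "overhang_b": base.overhang_a,
                }
            )
        else:  # trans-chromosome: move the acceptor-side segment to another gene
            other = _other_chrom_site(decoy_sites, gene, rng)
            if other is None:
                rec = ChimericRecord(
                    **{**asdict(base), "strand_b": "-" if gene.strand == "+" else "+"}
                )
            else:
                ogene, oacc, odon = other
                d = asdict(base)
                if gene.strand == "+":
                    # seg_b carries the acceptor (its start)
                    d.update(chrom_b=ogene.chrom, start_b=oacc, end_b=oacc + base.overhang_b)
                else:
                    # seg_b carries the donor (its end)
                    d.update(chrom_b=ogene.chrom, start_b=odon - base.overhang_b, end_b=odon)
                rec = ChimericRecord(**d)
        records.append(rec)
        truth.decoy_records.append((rid, 1))

    # class 2: one overhang below the threshold
    for i in range(decoys_per_class):
        gene, acc, don = site(int(rng.integers(len(decoy_sites))))
        lib = libraries[i % len(libraries)]
        rid = f"decoy2_{i}"
        records.append(
            _passing_record(
                rng, rid, lib, gene.chrom, gene.strand, acc, don, config, split=11,
            )
        )
        truth.decoy_records.append((rid, 2))

    # class 3: score margin exactly at the (non-passing) boundary
    for i in range(decoys_per_class):
        gene, acc, don = site(int(rng.integers(len(decoy_sites))))
        lib = libraries[i % len(libraries)]
        rid = f"decoy3_{i}"
        records.append(
            _passing_record(
                rng, rid, lib, gene.chrom, gene.strand, acc, don, config, margin=2,
            )
        )
        truth.decoy_records.append((rid, 3))

    # class 4: junction at non-annotated, non-canonical coordinates
    for i in range(decoys_per_class):
        gene, acc, don = _noncanonical_site(genome, annotation, rng, config)
        lib = libraries[i % len(libraries)]
        rid = f"decoy4_{i}"
        records.append(
            _passing_record(rng, rid, lib, gene.chrom, gene.strand, acc, don, config)
        )
        truth.decoy_records.append((rid, 4))

    if truth_spec:
        order = rng.permutation(len(records))
        records = [records[i] for i in order]
    return records, truth


def _other_chrom_site(decoy_sites, gene, rng):
    options = [s for s in decoy_sites if s[0].chrom != gene.chrom and s[0].strand == gene.strand]
    if not options:
        return None
    return options[int(rng.integers(len(options)))]


def _noncanonical_site(genome, annotation, rng, config):
    genes = [g for g in annotation.genes if g.end - g.start >= config.read_length + 40]
    for _ in range(10_000):
        gene = genes[int(rng.integers(len(genes)))]
        seq = genome[gene.chrom]
        acc = int(rng.integers(gene.start + 5, gene.end - config.read_length - 5))
        don = int(rng.integers(acc + config.read_length, gene.end))
        if annotation.genes_at_exon_start(gene.chrom, gene.strand, acc):
            continue
        if annotation.genes_at_exon_end(gene.chrom, gene.strand, don):
            continue
        left = seq[acc - 2 : acc]
        right = seq[don : don + 2]
        if gene.strand == "+" and (left == "AG" and right == "GT"):
            continue
        if gene.strand == "-" and (left == "AC" and right == "CT"):
            continue
        # break the canonical pair entirely so the criterion fails cleanly
        if gene.strand == "+" and (left == "AG" or right == "GT"):
            continue
        if gene.strand == "-" and (left == "AC" or right == "CT"):
            continue
        return gene, acc, don
    raise TruthSpecError("could not find a non-canonical decoy site")


# ---------------------------------------------------------------------------
# SAM writer (chimeric records as primary + supplementary pairs)
# ---------------------------------------------------------------------------

def write_sam(
    records: Sequence[ChimericRecord], genome: dict[str, str], path: str | os.PathLike
) -> None:
    """Write records as SAM with SA-tagged segment pairs and a secondary
    linear alignment carrying the best linear score."""
    from .models import revcomp

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in records:
            la, lb = r.overhang_a, r.overhang_b
            part_a = genome[r.chrom_a][r.start_a : r.end_a]
            part_b = genome[r.chrom_b][r.start_b : r.end_b]
            if r.strand_a == "-":
                read = revcomp(part_a) + (revcomp(part_b) if r.strand_b == "-" else part_b)
            else:
                read = part_a + (revcomp(part_b) if r.strand_b == "-" else part_b)
            rev_a = r.strand_a == "-"
            rev_b = r.strand_b == "-"
            # CIGARs in reference orientation; read-leading clip sits at the
            # cigar end for reverse-mapped segments.
            cig_a = f"{lb}S{la}M" if rev_a else f"{la}M{lb}S"
            cig_b = f"{lb}M{la}S" if rev_b else f"{la}S{lb}M"
            seq_a = revcomp(read) if rev_a else read
            seq_b = revcomp(read) if rev_b else read
            sa_b = f"{r.chrom_b},{r.start_b + 1},{'-' if rev_b else '+'},{cig_b},60,0;"
            sa_a = f"{r.chrom_a},{r.start_a + 1},{'-' if rev_a else '+'},{cig_a},60,0;"
            flag_a = 16 if rev_a else 0
            flag_b = (2048 | 16) if rev_b else 2048
            fh.write(
                f"{r.record_id}\t{flag_a}\t{r.chrom_a}\t{r.start_a + 1}\t60\t{cig_a}\t*\t0\t0\t"
                f"{seq_a}\t*\tAS:i:{r.chimeric_score}\tSA:Z:{sa_b}\tRG:Z:{r.library_id}\n"
            )
            fh.write(
                f"{r.record_id}\t{flag_b}\t{r.chrom_b}\t{r.start_b + 1}\t60\t{cig_b}\t*\t0\t0\t"
                f"{seq_b}\t*\tAS:i:{r.chimeric_score}\tSA:Z:{sa_a}\tRG:Z:{r.library_id}\n"
            )
            fh.write(
                f"{r.record_id}\t256\t{r.chrom_a}\t{min(r.start_a, r.start_b) + 1}\t0\t"
                f"{len(read)}M\t*\t0\t0\t*\t*\tAS:i:{r.best_linear_score}\tRG:Z:{r.library_id}\n"
            )


# ---------------------------------------------------------------------------
# SELEX simulation
# ---------------------------------------------------------------------------

def simulate_selex(
    config: SimConfig,
    layout: Optional[LibraryLayout] = None,
    out_dir: Optional[str | os.PathLike] = None,
) -> tuple[dict[int, list[str]], Optional[dict[int, str]], LibraryLayout, TruthTable]:
    """Iterative selection on a random 20-mer pool with planted motif affinity.

    Round 0 is a uniform random pool.  Each round keeps a tag with
    probability ``sigmoid(stringency_r * (affinity_score - midpoint))``
    where the affinity score sums ``affinity_weights`` over motif
    occurrences, then resamples with replacement back to ``pool_size``.
    When ``out_dir`` is given, each round is written as FASTQ with the
    layout's barcode/primer/random-barcode structure.
    """
    if config.pool_size < 10_000:
        raise ConfigurationError("pool_size must be >= 10^4")
    if not config.affinity_weights:
        raise ConfigurationError("affinity_weights must be non-empty")
    if len(config.stringency_schedule) != config.rounds:
        raise ConfigurationError(
            f"stringency_schedule length {len(config.stringency_schedule)} != rounds {config.rounds}"
        )
    ks = {len(m) for m in config.affinity_weights}
    if len(ks) != 1:
        raise ConfigurationError("affinity motifs must share one length")
    k = ks.pop()
    layout = layout or default_selex_layout(config.rounds)
    rng = config.rng(3)

    weights = np.zeros(4**k)
    for motif, w in config.affinity_weights.items():
        weights[_kmers.motif_code(motif)] = float(w)

    pool = rng.integers(0, 4, size=(config.pool_size, config.tag_length), dtype=np.int8)
    pools_by_round: dict[int, np.ndarray] = {0: pool}
    for r in range(1, config.rounds + 1):
        stringency = float(config.stringency_schedule[r - 1])
        scores = _kmers.weighted_scores(pools_by_round[r - 1], weights, k)
        p = 1.0 / (1.0 + np.exp(-stringency * (scores - config.survival_midpoint)))
        keep = rng.random(len(p)) < p
        survivors = pools_by_round[r - 1][keep]
        if len(survivors) == 0:
            raise ConfigurationError("no tags survived selection; lower the stringency")
        idx = rng.integers(0, len(survivors), size=config.pool_size)
        pools_by_round[r] = survivors[idx]

    pools_str = {
        r: [row.tobytes() for row in _BASE_BYTES[arr]]
        for r, arr in pools_by_round.items()
    }
    pools_decoded = {r: [b.decode("ascii") for b in rows] for r, rows in pools_str.items()}

    fastq_paths = None
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        fastq_paths = {}
        for r, tags in pools_decoded.items():
            sample = f"R{r}"
            path = os.path.join(out_dir, f"{sample}.fastq")
            _write_selex_fastq(path, sample, tags, layout, rng)
            fastq_paths[r] = path
    best = max(config.affinity_weights, key=lambda m: config.affinity_weights[m])
    truth = TruthTable(true_selex_motif=best)
    return pools_decoded, fastq_paths, layout, truth


def _write_selex_fastq(
    path: str, sample: str, tags: Sequence[str], layout: LibraryLayout, rng: np.random.Generator
) -> None:
    bc = layout.sample_barcodes[sample]
    rb_len = layout.random_barcode_length
    rbs = _BASE_BYTES[rng.integers(0, 4, size=(len(tags), rb_len), dtype=np.int8)]
    lines = []
    for i, tag in enumerate(tags):
        rb = rbs[i].tobytes().decode("ascii")
        if layout.random_barcode_side == "5p":
            seq = bc + rb + layout.primer_5p + tag + layout.primer_3p
        else:
            seq = bc + layout.primer_5p + tag + layout.primer_3p + rb
        lines.append(f"@{sample}_{i}\n{seq}\n+\n{'I' * len(seq)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def mean_motif_occurrences(pool: Sequence[str], motif: str) -> float:
    """Mean overlapping occurrences of one motif per tag (truth-side oracle)."""
    k = len(motif)
    code = np.array([_kmers.motif_code(motif)], dtype=np.int64)
    arr = _kmers.encode_block(list(pool), len(pool[0]))
    codes, valid = _kmers.window_codes(arr, k)
    hits = np.isin(codes, code) & valid
    return float(hits.sum(axis=1).mean())


# ---------------------------------------------------------------------------
# circRNA sequence groups
# ---------------------------------------------------------------------------

def simulate_circ_groups(
    config: SimConfig,
    n_target: int = 34,
    n_nontarget: int = 117,
    offset: float = 5.0,
    motifs: Optional[Sequence[str]] = None,
    length_range: tuple[int, int] = (200, 2000),
) -> tuple[dict[str, str], dict[str, str]]:
    """Two circRNA sequence groups differing by a planted motif-density offset.

    Non-target sequences are i.i.d. background; target sequences receive
    ``round(offset * length / 100)`` planted occurrences drawn from the
    motif list at random positions.
    """
    if n_target < 2 or n_nontarget < 2:
        raise ConfigurationError("group sizes must be >= 2")
    if offset < 0:
        raise ConfigurationError("density offset must be >= 0")
    motifs = list(motifs) if motifs else list(DEFAULT_AFFINITY)
    k = len(motifs[0])
    rng = config.rng(4)
    lo, hi = length_range

    def background(n):
        return _random_seq_array(rng, n, config.gc_fraction)

    targets: dict[str, str] = {}
    nontargets: dict[str, str] = {}
    for i in range(n_target):
        length = int(rng.integers(lo, hi + 1))
        arr = background(length)
        n_plant = int(round(offset * length / 100.0))
        if n_plant:
            positions = rng.integers(0, length - k + 1, size=n_plant)
            for pos in positions:
                motif = motifs[int(rng.integers(len(motifs)))]
                arr[pos : pos + k] = np.frombuffer(motif.encode(), dtype=np.uint8)
        targets[f"target_{i + 1:03d}"] = arr.tobytes().decode("ascii")
    for i in range(n_nontarget):
        length = int(rng.integers(lo, hi + 1))
        nontargets[f"nontarget_{i + 1:03d}"] = background(length).tobytes().decode("ascii")
    return targets, nontargets
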