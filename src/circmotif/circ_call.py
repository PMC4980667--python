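"""Back-splice junction calling from chimeric alignment records.

A chimeric record carries the two segments of one read in *read order*
(``seg_a`` is the first part of the read).  A back-splice signature means the
segments map to the same chromosome and strand but in reverse genomic order:
on ``+`` the first read segment lies genomically *right* of the second, on
``-`` the convention mirrors (first segment genomically left).  The implied
junction is the genomic-leftmost segment start (acceptor) paired with the
genomic-rightmost segment end (donor, exclusive).

Acceptance requires all four criteria:

* C1  same chromosome, same strand, reverse genomic order;
* C2  both junction overhangs >= ``min_overhang`` (default 12 nt);
* C3  chimeric score strictly more than ``score_margin`` above the best
  linear alignment score (default margin 2, i.e. difference >= 3);
* C4  both splice sites annotated exon boundaries of one gene, or
  canonical GT/AG flanks in back-splice orientation.
"""

from __future__ import annotations

import csv
import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ChimericTableFormatError
from .models import Annotation, GeneModel, revcomp

logger = logging.getLogger(__name__)

CHIMERIC_COLUMNS = [
    "record_id",
    "library_id",
    "chrom_a",
    "start_a",
    "end_a",
    "strand_a",
    "chrom_b",
    "start_b",
    "end_b",
    "strand_b",
    "chimeric_score",
    "best_linear_score",
]

INTERGENIC = "intergenic"


@dataclass(frozen=True)
class ChimericRecord:
    """One read's two-segment chimeric mapping (segments in read order)."""

    record_id: str
    library_id: str
    chrom_a: str
    start_a: int
    end_a: int
    strand_a: str
    chrom_b: str
    start_b: int
    end_b: int
    strand_b: str
    chimeric_score: int
    best_linear_score: int
    overhang_a: int = -1
    overhang_b: int = -1

    def __post_init__(self):
        if self.start_a >= self.end_a or self.start_b >= self.end_b:
            raise ValueError(f"{self.record_id}: segment interval start must be < end")
        if self.overhang_a < 0:
            object.__setattr__(self, "overhang_a", self.end_a - self.start_a)
        if self.overhang_b < 0:
            object.__setattr__(self, "overhang_b", self.end_b - self.start_b)
        if self.overhang_a < 1 or self.overhang_b < 1:
            raise ValueError(f"{self.record_id}: overhangs must be >= 1")


@dataclass
class BackspliceJunction:
    """Strand-aware back-splice coordinates with per-library read counts."""

    chrom: str
    strand: str
    acceptor_pos: int  # 0-based first nt of the circle (genomic leftmost)
    donor_pos: int  # 0-based exclusive end of the circle (genomic rightmost)
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.acceptor_pos >= self.donor_pos:
            raise ValueError("acceptor_pos must be < donor_pos")

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.chrom, self.strand, self.acceptor_pos, self.donor_pos)

    @property
    def max_count(self) -> int:
        return max(self.counts.values()) if self.counts else 0


@dataclass
class CircCandidate:
    junction: BackspliceJunction
    gene_id: str
    gene_biotype: str
    n_exons: int
    circ_length: int
    status: str  # high_confidence | detected | non_target


@dataclass
class FilterParams:
    min_overhang: int = 12
    score_margin: int = 2
    high_conf_threshold: int = 30
    nontarget_min_count: int = 10
    require_biotype: str = "protein_coding"

    def __post_init__(self):
        for name in ("min_overhang", "score_margin", "high_conf_threshold", "nontarget_min_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

def read_chimeric_table(
    path: str | os.PathLike, strict: bool = False
) -> tuple[list[ChimericRecord], list[tuple[int, str]]]:
    """Parse the 12-column chimeric TSV dialect.

    Input coordinates are 1-based inclusive and are converted to 0-based
    half-open.  Malformed rows are collected as ``(line_number, message)``
    pairs; with ``strict`` the first malformed row raises.
    """
    records: list[ChimericRecord] = []
    errors: list[tuple[int, str]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ChimericTableFormatError(f"{path}: empty file, header required")
        if header != CHIMERIC_COLUMNS:
            raise ChimericTableFormatError(
                f"{path}: bad header; expected {CHIMERIC_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(CHIMERIC_COLUMNS):
                msg = f"expected {len(CHIMERIC_COLUMNS)} columns, got {len(row)}"
                if strict:
                    raise ChimericTableFormatError(f"{path}:{lineno}: {msg}")
                errors.append((lineno, msg))
                continue
            try:
                records.append(
                    ChimericRecord(
                        record_id=row[0],
                        library_id=row[1],
                        chrom_a=row[2],
                        start_a=int(row[3]) - 1,
                        end_a=int(row[4]),
                        strand_a=row[5],
                        chrom_b=row[6],
                        start_b=int(row[7]) - 1,
                        end_b=int(row[8]),
                        strand_b=row[9],
                        chimeric_score=int(row[10]),
                        best_linear_score=int(row[11]),
                    )
                )
            except (ValueError, TypeError) as exc:
                if strict:
                    raise ChimericTableFormatError(f"{path}:{lineno}: {exc}") from exc
                errors.append((lineno, str(exc)))
    return records, errors


def write_chimeric_table(records: Iterable[ChimericRecord], path: str | os.PathLike) -> None:
    """Write records in the 1-based-inclusive TSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(CHIMERIC_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.record_id,
                    r.library_id,
                    r.chrom_a,
                    r.start_a + 1,
                    r.end_a,
                    r.strand_a,
                    r.chrom_b,
                    r.start_b + 1,
                    r.end_b,
                    r.strand_b,
                    r.chimeric_score,
                    r.best_linear_score,
                ]
            )


JUNCTION_COLUMNS = ["chrom", "strand", "acceptor", "donor", "library_id", "count"]


def write_junction_table(junctions: Iterable[BackspliceJunction], path: str | os.PathLike) -> None:
    """Long-format junction TSV (1-based inclusive coordinates)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(JUNCTION_COLUMNS)
        for j in junctions:
            for lib in sorted(j.counts):
                writer.writerow([j.chrom, j.strand, j.acceptor_pos + 1, j.donor_pos, lib, j.counts[lib]])


def read_junction_table(path: str | os.PathLike) -> list[BackspliceJunction]:
    by_key: dict[tuple, BackspliceJunction] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != JUNCTION_COLUMNS:
            raise ChimericTableFormatError(f"{path}: bad junction header {header}")
        for row in reader:
            if not row:
                continue
            chrom, strand, acc, don, lib, count = row
            key = (chrom, strand, int(acc) - 1, int(don))
            j = by_key.get(key)
            if j is None:
                j = by_key[key] = BackspliceJunction(chrom, strand, int(acc) - 1, int(don))
            j.counts[lib] = j.counts.get(lib, 0) + int(count)
    return sorted(by_key.values(), key=lambda j: j.key)


# ---------------------------------------------------------------------------
# SAM adapter
# ---------------------------------------------------------------------------

def extract_from_sam(
    path: str | os.PathLike,
    genome: Optional[dict[str, str]] = None,
    annotation: Optional[Annotation] = None,
    default_library: str = "lib1",
) -> list[ChimericRecord]:
    """Assemble chimeric records from primary + SA-tagged supplementary pairs.

    ``best_linear_score`` is taken from the best AS of a non-chimeric
    alignment of the same read when present, otherwise recomputed by the
    ungapped fallback scorer against the genomic window spanning both
    segments (+/- 500 nt) and overlapping transcript sequences.
    """
    import pysam

    chimeric: dict[str, list] = defaultdict(list)
    linear_best: dict[str, int] = {}
    read_seq: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            qname = aln.query_name
            if aln.has_tag("SA"):
                if not aln.is_secondary:
                    chimeric[qname].append(aln)
                    if aln.query_sequence and not aln.is_supplementary:
                        seq = aln.query_sequence
                        if aln.is_reverse:
                            seq = revcomp(seq)
                        read_seq[qname] = seq
            else:
                if aln.has_tag("AS"):
                    score = int(aln.get_tag("AS"))
                    if score > linear_best.get(qname, -(10**9)):
                        linear_best[qname] = score

    out: list[ChimericRecord] = []
    for qname in sorted(chimeric):
        segs = chimeric[qname]
        if len(segs) != 2:
            logger.warning("read %s has %d chimeric segments; skipped", qname, len(segs))
            continue
        segs = sorted(segs, key=_read_start_offset)
        a, b = segs
        chim_score = None
        for s in segs:
            if not s.is_supplementary and s.has_tag("AS"):
                chim_score = int(s.get_tag("AS"))
        if chim_score is None:
            chim_score = max(int(s.get_tag("AS")) for s in segs if s.has_tag("AS"))
        if qname in linear_best:
            lin = linear_best[qname]
        else:
            lin = _fallback_linear_score(qname, segs, read_seq.get(qname), genome, annotation)
        out.append(
            ChimericRecord(
                record_id=qname,
                library_id=_library_of(a, default_library),
                chrom_a=a.reference_name,
                start_a=a.reference_start,
                end_a=a.reference_end,
                strand_a="-" if a.is_reverse else "+",
                chrom_b=b.reference_name,
                start_b=b.reference_start,
                end_b=b.reference_end,
                strand_b="-" if b.is_reverse else "+",
                chimeric_score=chim_score,
                best_linear_score=lin,
                overhang_a=a.query_alignment_length,
                overhang_b=b.query_alignment_length,
            )
        )
    return out


def _library_of(aln, default: str) -> str:
    try:
        return str(aln.get_tag("RG"))
    except KeyError:
        return default


def _read_start_offset(aln) -> int:
    """Offset of the aligned block within the original read, from clipping."""
    cigar = aln.cigartuples or []
    if not cigar:
        return 0
    lead = cigar[-1] if aln.is_reverse else cigar[0]
    return lead[1] if lead[0] in (4, 5) else 0  # S or H


def ungapped_local_score(read: str, ref: str, match: int = 1, mismatch: int = -1) -> int:
    """Best ungapped local alignment score over all diagonals (Kadane)."""
    if not read or not ref:
        return 0
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    t = np.frombuffer(ref.encode(), dtype=np.uint8)
    best = 0
    for offset in range(-len(r) + 1, len(t)):
        lo_r = max(0, -offset)
        lo_t = lo_r + offset
        n = min(len(r) - lo_r, len(t) - lo_t)
        if n <= 0:
            continue
        scores = np.where(r[lo_r : lo_r + n] == t[lo_t : lo_t + n], match, mismatch)
        run = 0
        for s in scores:
            run = max(0, run + int(s))
            if run > best:
                best = run
    return best


def _fallback_linear_score(qname, segs, seq, genome, annotation) -> int:
    if seq is None or genome is None:
        logger.warning("read %s: no linear alignment and no fallback inputs; margin set to 0", qname)
        return max(int(s.get_tag("AS")) for s in segs if s.has_tag("AS"))
    chrom = segs[0].reference_name
    lo = max(0, min(s.reference_start for s in segs if s.reference_name == chrom) - 500)
    hi = min(len(genome[chrom]), max(s.reference_end for s in segs if s.reference_name == chrom) + 500)
    best = ungapped_local_score(seq, genome[chrom][lo:hi])
    best = max(best, ungapped_local_score(revcomp(seq), genome[chrom][lo:hi]))
    if annotation is not None:
        for g in annotation.genes_overlapping(chrom, lo, hi):
            tx = g.spliced_sequence(genome)
            best = max(best, ungapped_local_score(seq, tx), ungapped_local_score(revcomp(seq), tx))
    return best


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def implied_junction(record: ChimericRecord) -> Optional[BackspliceJunction]:
    """Junction implied by a same-chromosome record: leftmost start / rightmost end."""
    if record.chrom_a != record.chrom_b:
        return None
    acc = min(record.start_a, record.start_b)
    don = max(record.end_a, record.end_b)
    if acc >= don:
        return None
    return BackspliceJunction(record.chrom_a, record.strand_a, acc, don)


def canonical_or_annotated(
    junction: BackspliceJunction, genome: dict[str, str], annotation: Annotation
) -> tuple[bool, str]:
    """Criterion-4 test for one junction.

    Annotated: acceptor equals an exon start and donor an exon end of the
    same gene on the same strand.  Canonical (back-splice orientation): on
    ``+`` the genome reads AG immediately left of the acceptor and GT
    immediately right of the donor; on ``-`` the reverse complement
    arrangement (AC left, CT right).
    """
    chrom, strand = junction.chrom, junction.strand
    seq = genome.get(chrom)
    if seq is None:
        return False, "neither"
    acc, don = junction.acceptor_pos, junction.donor_pos
    annotated = bool(
        annotation.genes_at_exon_start(chrom, strand, acc)
        & annotation.genes_at_exon_end(chrom, strand, don)
    )
    canonical = False
    if acc - 2 >= 0 and don + 2 <= len(seq):
        left = seq[acc - 2 : acc]
        right = seq[don : don + 2]
        if strand == "+":
            canonical = left == "AG" and right == "GT"
        else:
            canonical = left == "AC" and right == "CT"
    else:
        logger.debug("junction %s flank window off chromosome end", junction.key)
    if annotated and canonical:
        return True, "both"
    if annotated:
        return True, "annotated"
    if canonical:
        return True, "canonical"
    return False, "neither"


def _canonical_flank(genome: dict[str, str], chrom: str, pos: int, strand: str, side: str) -> bool:
    """Per-side canonical flank check (used when segments span chromosomes)."""
    seq = genome.get(chrom)
    if seq is None:
        return False
    if side == "acceptor":
        if pos - 2 < 0:
            return False
        want = "AG" if strand == "+" else "AC"
        return seq[pos - 2 : pos] == want
    if pos + 2 > len(seq):
        return False
    want = "GT" if strand == "+" else "CT"
    return seq[pos : pos + 2] == want


def criterion_flags(
    record: ChimericRecord,
    genome: dict[str, str],
    annotation: Annotation,
    params: FilterParams,
) -> dict:
    """Evaluate each selection criterion independently for one record."""
    r = record
    same_chrom = r.chrom_a == r.chrom_b
    same_strand = r.strand_a == r.strand_b
    if r.strand_a == "+":
        reverse_order = r.start_a > r.start_b
    else:
        reverse_order = r.start_a < r.start_b
    c1 = same_chrom and same_strand and reverse_order
    c2 = min(r.overhang_a, r.overhang_b) >= params.min_overhang
    c3 = (r.chimeric_score - r.best_linear_score) > params.score_margin

    label = "neither"
    in_bounds = True
    if same_chrom:
        seq = genome.get(r.chrom_a)
        junction = implied_junction(r)
        if seq is None or junction is None or junction.donor_pos > len(seq) or junction.acceptor_pos < 0:
            c4 = False
            in_bounds = False
        else:
            c4, label = canonical_or_annotated(junction, genome, annotation)
    else:
        # Junction boundaries live on two chromosomes; check each side on
        # its own chromosome following the read-order convention.
        if r.strand_a == "+":
            acc_ok = _canonical_flank(genome, r.chrom_b, r.start_b, r.strand_a, "acceptor")
            don_ok = _canonical_flank(genome, r.chrom_a, r.end_a, r.strand_a, "donor")
        else:
            acc_ok = _canonical_flank(genome, r.chrom_a, r.start_a, r.strand_a, "acceptor")
            don_ok = _canonical_flank(genome, r.chrom_b, r.end_b, r.strand_a, "donor")
        c4 = acc_ok and don_ok
        label = "canonical" if c4 else "neither"
    return {
        "record_id": r.record_id,
        "library_id": r.library_id,
        "c1": c1,
        "c2": c2,
        "c3": c3,
        "c4": c4,
        "c4_label": label,
        "in_bounds": in_bounds,
        "accepted": c1 and c2 and c3 and c4 and in_bounds,
    }


def apply_filters(
    records: Sequence[ChimericRecord],
    genome: dict[str, str],
    annotation: Annotation,
    params: Optional[FilterParams] = None,
) -> tuple[list[ChimericRecord], pd.DataFrame]:
    """Apply the four selection criteria; returns accepted records + flag table."""
    params = params or FilterParams()
    rows = [criterion_flags(r, genome, annotation, params) for r in records]
    flags = pd.DataFrame(
        rows,
        columns=["record_id", "library_id", "c1", "c2", "c3", "c4", "c4_label", "in_bounds", "accepted"],
    )
    accepted = [r for r, row in zip(records, rows) if row["accepted"]]
    return accepted, flags


def count_junctions(accepted: Sequence[ChimericRecord]) -> list[BackspliceJunction]:
    """Group accepted records into per-library junction read counts.

    Duplicate ``record_id`` values within a library are counted once.
    """
    seen: set[tuple[str, str]] = set()
    counts: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for r in accepted:
        dedup_key = (r.record_id, r.library_id)
        if dedup_key in seen:
            continue
        seen.add(dedup_key)
        j = implied_junction(r)
        if j is None:
            continue
        counts[j.key][r.library_id] += 1
    out = [
        BackspliceJunction(chrom, strand, acc, don, dict(libs))
        for (chrom, strand, acc, don), libs in counts.items()
    ]
    return sorted(out, key=lambda j: j.key)


# ---------------------------------------------------------------------------
# Candidate annotation and group selection
# ---------------------------------------------------------------------------

def _host_gene(junction: BackspliceJunction, annotation: Annotation) -> Optional[GeneModel]:
    exact = annotation.genes_at_exon_start(
        junction.chrom, junction.strand, junction.acceptor_pos
    ) & annotation.genes_at_exon_end(junction.chrom, junction.strand, junction.donor_pos)
    if exact:
        return annotation.gene(min(exact))
    overlapping = annotation.genes_overlapping(
        junction.chrom, junction.acceptor_pos, junction.donor_pos, junction.strand
    )
    if not overlapping:
        return None

    def overlap(g: GeneModel) -> int:
        return min(g.end, junction.donor_pos) - max(g.start, junction.acceptor_pos)

    return sorted(overlapping, key=lambda g: (-overlap(g), g.gene_id))[0]


def annotate_junction(junction: BackspliceJunction, annotation: Annotation) -> CircCandidate:
    gene = _host_gene(junction, annotation)
    if gene is None:
        return CircCandidate(
            junction=junction,
            gene_id=INTERGENIC,
            gene_biotype="NA",
            n_exons=0,
            circ_length=junction.donor_pos - junction.acceptor_pos,
            status="detected",
        )
    inside = [
        (s, e)
        for s, e in gene.exons
        if junction.acceptor_pos <= s and e <= junction.donor_pos
    ]
    circ_length = sum(e - s for s, e in inside)
    if not inside:
        circ_length = junction.donor_pos - junction.acceptor_pos
    return CircCandidate(
        junction=junction,
        gene_id=gene.gene_id,
        gene_biotype=gene.biotype,
        n_exons=len(inside),
        circ_length=circ_length,
        status="detected",
    )


def select_targets(
    junctions: Sequence[BackspliceJunction],
    annotation: Annotation,
    params: Optional[FilterParams] = None,
) -> list[CircCandidate]:
    """Annotate counted junctions and mark the high-confidence set.

    A candidate is ``high_confidence`` when its junction reaches the read
    threshold in at least one library.
    """
    params = params or FilterParams()
    out = []
    for j in junctions:
        cand = annotate_junction(j, annotation)
        cand.status = (
            "high_confidence" if j.max_count >= params.high_conf_threshold else "detected"
        )
        out.append(cand)
    return out


def derive_nontarget_group(
    expression_junctions: Sequence[BackspliceJunction],
    ip_junctions: Sequence[BackspliceJunction],
    annotation: Annotation,
    params: Optional[FilterParams] = None,
) -> list[CircCandidate]:
    """Select the non-target comparison group from expression-library junctions.

    Kept junctions are well-expressed (count >= threshold in some library),
    hosted by a gene of the required biotype, and strictly absent from the
    IP-detected set (any IP read disqualifies).
    """
    params = params or FilterParams()
    ip_keys = {j.key for j in ip_junctions if j.max_count >= 1}
    out = []
    for j in expression_junctions:
        if j.max_count < params.nontarget_min_count:
            continue
        if j.key in ip_keys:
            continue
        cand = annotate_junction(j, annotation)
        if cand.gene_id == INTERGENIC or cand.gene_biotype != params.require_biotype:
            continue
        cand.status = "non_target"
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_candidates_tsv(candidates: Sequence[CircCandidate], path: str | os.PathLike) -> None:
    libs = sorted({lib for c in candidates for lib in c.junction.counts})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["chrom", "strand", "acceptor", "donor", "gene_id", "gene_biotype", "n_exons", "circ_length", "status"]
            + [f"count_{lib}" for lib in libs]
        )
        for c in candidates:
            j = c.junction
            writer.writerow(
                [j.chrom, j.strand, j.acceptor_pos + 1, j.donor_pos, c.gene_id, c.gene_biotype, c.n_exons, c.circ_length, c.status]
                + [j.counts.get(lib, 0) for lib in libs]
            )


def write_junctions_bed(candidates: Sequence[CircCandidate], path: str | os.PathLike) -> None:
    """BED6: 0-based half-open, name = gene|n_exons|circ_length, score = max count."""
    with open(path, "w") as fh:
        for c in sorted(candidates, key=lambda c: c.junction.key):
            j = c.junction
            name = f"{c.gene_id}|{c.n_exons}|{c.circ_length}"
            score = min(1000, j.max_count)
            fh.write(
                f"{j.chrom}\t{j.acceptor_pos}\t{j.donor_pos}\t{name}\t{score}\t{j.strand}\n"
            )


def rejection_tally(flags: pd.DataFrame) -> dict[str, int]:
    """Per-criterion failure counts (a record may fail several)."""
    return {
        "total": int(len(flags)),
        "accepted": int(flags["accepted"].sum()),
        "fail_c1": int((~flags["c1"]).sum()),
        "fail_c2": int((~flags["c2"]).sum()),
        "fail_c3": int((~flags["c3"]).sum()),
        "fail_c4": int((~flags["c4"]).sum()),
        "out_of_bounds": int((~flags["in_bounds"]).sum()),
    }
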