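"""SELEX-seq tag preprocessing and per-round k-mer enrichment z-scores.

Reads are demultiplexed by exact sample barcode, trimmed of both PCR
primers, deduplicated on the (random barcode, insert) pair, and restricted
to the configured tag length range.  Enrichment standardises each motif's
per-round presence count against the full motif population of the same
length (population standard deviation) and ranks motifs by the sum of the
per-round z-scores over selection rounds.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import _kmers
from .errors import LayoutError

logger = logging.getLogger(__name__)


@dataclass
class LibraryLayout:
    """Read structure of a SELEX sequencing library.

    Layout in read order: sample barcode, then (if ``random_barcode_side``
    is ``5p``) the random barcode, the 5' primer, the insert, the 3' primer,
    and (if ``3p``) the random barcode.
    """

    sample_barcodes: dict[str, str]
    primer_5p: str
    primer_3p: str
    random_barcode_length: int = 5
    random_barcode_side: str = "5p"
    tag_length_range: tuple[int, int] = (18, 20)

    def __post_init__(self):
        self.tag_length_range = tuple(self.tag_length_range)  # type: ignore[assignment]
        bcs = list(self.sample_barcodes.values())
        if not bcs or any(not b for b in bcs):
            raise LayoutError("sample barcodes must be non-empty")
        if len(set(bcs)) != len(bcs):
            raise LayoutError("sample barcodes must be unique")
        for a in bcs:
            for b in bcs:
                if a != b and b.startswith(a):
                    raise LayoutError(f"barcode {a} is a prefix of {b}")
        if self.random_barcode_side not in ("5p", "3p"):
            raise LayoutError("random_barcode_side must be '5p' or '3p'")
        lo, hi = self.tag_length_range
        if lo > hi:
            raise LayoutError("tag_length_range min must be <= max")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "sample_barcodes": self.sample_barcodes,
                    "primer_5p": self.primer_5p,
                    "primer_3p": self.primer_3p,
                    "random_barcode_length": self.random_barcode_length,
                    "random_barcode_side": self.random_barcode_side,
                    "tag_length_range": list(self.tag_length_range),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "LibraryLayout":
        with open(path) as fh:
            data = json.load(fh)
        data["tag_length_range"] = tuple(data.get("tag_length_range", (18, 20)))
        return cls(**data)


def default_selex_layout(rounds: int = 4) -> LibraryLayout:
    """Layout used by the simulator: one sample per round R0..R<rounds>."""
    barcode_pool = [
        "AAGGA", "CCTTC", "GGAAT", "TTCCG", "ACACT", "GTGTC",
        "CAGTA", "TGACC", "AGGTT", "CTTGG",
    ]
    if rounds + 1 > len(barcode_pool):
        raise LayoutError(f"no default barcodes for {rounds + 1} samples")
    samples = {f"R{r}": barcode_pool[r] for r in range(rounds + 1)}
    return LibraryLayout(
        sample_barcodes=samples,
        primer_5p="GGGAGACAAGACTA",
        primer_3p="CTGTAGGCACCATC",
        random_barcode_length=5,
        random_barcode_side="5p",
    )


@dataclass
class TagPool:
    sample: str
    round: Optional[int]
    tags: list[str] = field(default_factory=list)


@dataclass
class KmerEnrichment:
    motif: str
    k: int
    count_per_round: dict[int, int]
    z_per_round: dict[int, float]
    z_cumulative: float


def _round_of(sample: str) -> Optional[int]:
    if len(sample) >= 2 and sample[0] in "Rr" and sample[1:].isdigit():
        return int(sample[1:])
    return None


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex_and_trim(
    fastq_paths: Sequence[str | os.PathLike] | str | os.PathLike,
    layout: LibraryLayout,
    max_mismatches: int = 0,
) -> tuple[dict[str, TagPool], dict[str, int]]:
    """Demultiplex, trim primers, dedup on (random barcode, insert).

    Returns per-sample tag pools plus rejection statistics keyed by reason
    (``unassigned``, ``primer_5p``, ``primer_3p``, ``tag_length``,
    ``duplicate``) and per-sample assignment counts.
    """
    if isinstance(fastq_paths, (str, os.PathLike)):
        fastq_paths = [fastq_paths]
    pools = {s: TagPool(sample=s, round=_round_of(s)) for s in layout.sample_barcodes}
    seen: dict[str, set[tuple[str, str]]] = {s: set() for s in pools}
    stats = {"total": 0, "unassigned": 0, "primer_5p": 0, "primer_3p": 0, "tag_length": 0, "duplicate": 0}
    by_prefix = sorted(layout.sample_barcodes.items(), key=lambda kv: -len(kv[1]))
    p5, p3 = layout.primer_5p, layout.primer_3p
    rb_len = layout.random_barcode_length
    lo, hi = layout.tag_length_range
    for path in fastq_paths:
        with open(path) as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                stats["total"] += 1
                seq = seq.upper()
                sample = None
                for name, bc in by_prefix:
                    if seq.startswith(bc):
                        sample = name
                        rest = seq[len(bc):]
                        break
                if sample is None:
                    stats["unassigned"] += 1
                    continue
                if layout.random_barcode_side == "5p":
                    rb, rest = rest[:rb_len], rest[rb_len:]
                else:
                    rb, rest = rest[-rb_len:] if rb_len else "", rest[: len(rest) - rb_len]
                if len(rest) < len(p5) or _mismatches(rest[: len(p5)], p5) > max_mismatches:
                    stats["primer_5p"] += 1
                    continue
                rest = rest[len(p5):]
                if len(rest) < len(p3) or _mismatches(rest[-len(p3):], p3) > max_mismatches:
                    stats["primer_3p"] += 1
                    continue
                insert = rest[: len(rest) - len(p3)]
                if not (lo <= len(insert) <= hi):
                    stats["tag_length"] += 1
                    continue
                key = (rb, insert)
                if key in seen[sample]:
                    stats["duplicate"] += 1
                    continue
                seen[sample].add(key)
                pools[sample].tags.append(insert)
    for s, pool in pools.items():
        stats[f"assigned_{s}"] = len(pool.tags)
    return pools, stats


def count_kmer_presence(pool: TagPool | Iterable[str], k: int) -> dict[str, int]:
    """Number of tags containing each of the 4**k motifs at least once."""
    if k not in (4, 6):
        raise ValueError("k must be 4 or 6")
    tags = pool.tags if isinstance(pool, TagPool) else list(pool)
    counts = _kmers.presence_counts(tags, k)
    motifs = _kmers.all_kmers(k)
    return dict(zip(motifs, counts.tolist()))


def kmer_zscores(
    counts_by_round: dict[int, dict[str, int]],
    selection_rounds: Optional[Sequence[int]] = None,
) -> list[KmerEnrichment]:
    """Standardise per-round motif counts across the motif population.

    ``z_cumulative`` sums z over selection rounds (every round > 0 present
    unless ``selection_rounds`` narrows it).  Rounds with zero variance
    across motifs get z = 0.  Result is sorted by descending cumulative z
    with alphabetical tiebreak.
    """
    rounds = sorted(counts_by_round)
    if not rounds:
        raise ValueError("no rounds supplied")
    motifs = sorted(counts_by_round[rounds[0]])
    k = len(motifs[0])
    if any(sorted(counts_by_round[r]) != motifs for r in rounds):
        raise ValueError("all rounds must cover the same motif set")
    if selection_rounds is None:
        selection_rounds = [r for r in rounds if r > 0]
    z_by_round: dict[int, np.ndarray] = {}
    for r in rounds:
        arr = np.array([counts_by_round[r][m] for m in motifs], dtype=float)
        sd = arr.std()  # population sd: the 4^k motifs are the full population
        if sd == 0:
            logger.warning("round %d: zero variance across motifs; z set to 0", r)
            z_by_round[r] = np.zeros_like(arr)
        else:
            z_by_round[r] = (arr - arr.mean()) / sd
    cumulative = np.zeros(len(motifs))
    for r in selection_rounds:
        cumulative += z_by_round[r]
    out = []
    for i, m in enumerate(motifs):
        out.append(
            KmerEnrichment(
                motif=m,
                k=k,
                count_per_round={r: int(counts_by_round[r][m]) for r in rounds},
                z_per_round={r: float(z_by_round[r][i]) for r in rounds},
                z_cumulative=float(cumulative[i]),
            )
        )
    out.sort(key=lambda e: (-e.z_cumulative, e.motif))
    return out


def rank_and_export(
    enrichments: Sequence[KmerEnrichment],
    out_path: Optional[str | os.PathLike] = None,
    top_n: int = 20,
    bottom_n: int = 10,
    control_z: Optional[dict[str, float]] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Heatmap-ready table of the top/bottom motifs plus the top-10 motif list."""
    ranked = sorted(enrichments, key=lambda e: (-e.z_cumulative, e.motif))
    chosen = ranked[:top_n] + (ranked[-bottom_n:] if bottom_n else [])
    rounds = sorted(ranked[0].z_per_round) if ranked else []
    rows = []
    for e in chosen:
        row = {"motif": e.motif}
        for r in rounds:
            row[f"z_R{r}"] = e.z_per_round[r]
        if control_z is not None:
            row["z_control"] = control_z.get(e.motif, float("nan"))
        row["z_cumulative"] = e.z_cumulative
        rows.append(row)
    df = pd.DataFrame(rows)
    top10 = [e.motif for e in ranked[:10]]
    if out_path is not None:
        df.to_csv(out_path, sep="\t", index=False)
    return df, top10


def write_tag_pool(pool: TagPool, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in pool.tags:
            fh.write(t + "\n")


def read_tag_file(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]
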