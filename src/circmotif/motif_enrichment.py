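"""Motif-density statistics: summed top-motif counts per 100 nt and the
target vs non-target group comparison (Welch t-test plus kernel density
estimates).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import _kmers
from .errors import EmptySequenceError, GroupSizeError

KDE_GRID_POINTS = 512


@dataclass
class MotifDensityRecord:
    circ_id: str
    group: str  # target | non_target
    length: int
    motif_count_sum: int
    density: float

    def __post_init__(self):
        expected = self.motif_count_sum / self.length * 100.0
        if abs(self.density - expected) > 1e-9:
            raise ValueError("density must equal motif_count_sum / length * 100")


@dataclass
class GroupComparison:
    n_target: int
    n_nontarget: int
    t_statistic: float
    dof: float
    p_value: float
    median_target: float
    median_nontarget: float
    kde_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_target": self.n_target,
                    "n_nontarget": self.n_nontarget,
                    "t_statistic": self.t_statistic,
                    "dof": self.dof,
                    "p_value": self.p_value,
                    "median_target": self.median_target,
                    "median_nontarget": self.median_nontarget,
                    "settings": self.settings,
                },
                fh,
                indent=2,
            )


def motif_occurrences(
    sequence: str,
    motifs: Sequence[str],
    overlapping: bool = True,
    circular: bool = False,
) -> int:
    """Total (by default overlapping) occurrences of any motif in a sequence.

    ``circular`` appends the first k-1 nt so junction-spanning occurrences
    are counted.  Windows containing non-ACGT characters are skipped with a
    single warning per sequence.
    """
    if not motifs:
        raise ValueError("motif set must be non-empty")
    lengths = {len(m) for m in motifs}
    if len(lengths) != 1:
        raise ValueError("all motifs must have equal length")
    k = lengths.pop()
    seq = sequence.upper()
    if circular and len(seq) >= k:
        seq = seq + seq[: k - 1]
    codes = [_kmers.motif_code(m) for m in motifs]
    count, had_invalid = _kmers.occurrence_count(seq, codes, k, overlapping=overlapping)
    if had_invalid:
        warnings.warn("sequence contains non-ACGT characters; those windows were skipped")
    return count


def densities(
    fasta_by_group: dict[str, dict[str, str]],
    motifs: Sequence[str],
    overlapping: bool = True,
    circular: bool = False,
) -> list[MotifDensityRecord]:
    """One density record per sequence: summed motif counts per 100 nt."""
    out = []
    for group, seqs in fasta_by_group.items():
        if not seqs:
            raise EmptySequenceError(f"group {group!r} has no sequences")
        for circ_id, seq in seqs.items():
            if not seq:
                raise EmptySequenceError(f"sequence {circ_id!r} is empty")
            count = motif_occurrences(seq, motifs, overlapping=overlapping, circular=circular)
            out.append(
                MotifDensityRecord(
                    circ_id=circ_id,
                    group=group,
                    length=len(seq),
                    motif_count_sum=count,
                    density=count / len(seq) * 100.0,
                )
            )
    return out


def welch_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, Welch-Satterthwaite dof, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            warnings.warn("both groups constant and equal; p set to 1")
            return 0.0, float(nx + ny - 2), 1.0
        t = float("inf") if x.mean() > y.mean() else float("-inf")
        return t, float(nx + ny - 2), 0.0
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    dof = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return float(t), float(dof), float(min(p, 1.0))


def _kde_curve(data: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if data.std(ddof=1) == 0:
        # degenerate group: represent as a narrow Gaussian around the value
        bw = max(1e-6, abs(data[0]) * 1e-3 + 1e-6)
        return stats.norm.pdf(grid, loc=data[0], scale=bw)
    kde = stats.gaussian_kde(data, bw_method="silverman")
    return kde(grid)


def compare_groups(
    records: Sequence[MotifDensityRecord],
    grid_points: int = KDE_GRID_POINTS,
    kde: bool = True,
) -> GroupComparison:
    """Welch comparison of target vs non-target densities with per-group KDEs."""
    x = np.array([r.density for r in records if r.group == "target"], dtype=float)
    y = np.array([r.density for r in records if r.group == "non_target"], dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise GroupSizeError("each group needs at least 2 records")
    t, dof, p = welch_ttest(x, y)
    comparison = GroupComparison(
        n_target=len(x),
        n_nontarget=len(y),
        t_statistic=t,
        dof=dof,
        p_value=p,
        median_target=float(np.median(x)),
        median_nontarget=float(np.median(y)),
        settings={
            "test": "welch_two_sample_two_sided",
            "kde_bandwidth": "silverman",
            "kde_grid_points": grid_points,
        },
    )
    if kde:
        pads = []
        for data in (x, y):
            sd = data.std(ddof=1)
            factor = stats.gaussian_kde(data, bw_method="silverman").factor if sd > 0 else 0.0
            pads.append(4.0 * factor * sd)
        pad = max(max(pads), 1e-6)
        lo = min(x.min(), y.min()) - pad
        hi = max(x.max(), y.max()) + pad
        grid = np.linspace(lo, hi, grid_points)
        comparison.kde_curves = {
            "target": (grid, _kde_curve(x, grid)),
            "non_target": (grid, _kde_curve(y, grid)),
        }
    return comparison


def write_densities_tsv(records: Sequence[MotifDensityRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("circ_id\tgroup\tlength\tmotif_count_sum\tdensity\n")
        for r in records:
            fh.write(f"{r.circ_id}\t{r.group}\t{r.length}\t{r.motif_count_sum}\t{r.density:.6f}\n")


def write_kde_tsv(comparison: GroupComparison, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("group\tx\tdensity\n")
        for group, (grid, curve) in comparison.kde_curves.items():
            for gx, gy in zip(grid, curve):
                fh.write(f"{group}\t{gx:.6f}\t{gy:.8f}\n")


def read_motif_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]
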