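"""RT-qPCR and gradient-profile quantitation utilities.

Covers primer-efficiency estimation from serial dilutions, percent-of-input
quantitation from cycle thresholds, and normalized sedimentation profiles
with peak-fraction shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EfficiencyFitError

N_FRACTIONS = 22


@dataclass
class QpcrAssay:
    target: str
    ct_input: float
    ct_ip: float
    input_fraction: float = 0.05
    efficiency: float = 2.0

    def __post_init__(self):
        if self.ct_input <= 0 or self.ct_ip <= 0:
            raise ValueError("Ct values must be > 0")
        if not (0 < self.input_fraction <= 1):
            raise ValueError("input_fraction must be in (0, 1]")
        if not (1 < self.efficiency <= 2):
            raise ValueError("efficiency must be in (1, 2]")


@dataclass
class GradientProfile:
    label: str
    intensities: Sequence[float]
    n_fractions: int = N_FRACTIONS

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.intensities) != self.n_fractions:
            raise ValueError(
                f"{self.label}: expected {self.n_fractions} fractions, got {len(self.intensities)}"
            )
        if (self.intensities < 0).any():
            raise ValueError(f"{self.label}: intensities must be >= 0")
        if not (self.intensities > 0).any():
            raise ValueError(f"{self.label}: at least one intensity must be nonzero")


@dataclass
class ProfileStats:
    label: str
    normalized: np.ndarray
    peak_fraction: int  # 1-based; lowest index on ties


def primer_efficiency(
    dilution_factors: Sequence[float], cts: Sequence[float]
) -> tuple[float, float, float]:
    """Fit Ct against log10(relative template amount).

    Returns ``(slope, r_squared, efficiency)`` with
    efficiency = 10**(-1/slope).  A non-negative slope is an error:
    amplification must reduce Ct with more template.
    """
    dil = np.asarray(dilution_factors, dtype=float)
    ct = np.asarray(cts, dtype=float)
    if len(dil) < 3:
        raise ValueError("need at least 3 dilution points")
    if (dil <= 0).any():
        raise ValueError("dilution factors must be strictly positive")
    x = np.log10(dil)
    slope, intercept = np.polyfit(x, ct, 1)
    if slope >= 0:
        raise EfficiencyFitError(f"slope {slope:.4f} >= 0: more template must lower Ct")
    residuals = ct - (slope * x + intercept)
    ss_res = float((residuals**2).sum())
    ss_tot = float(((ct - ct.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    efficiency = 10.0 ** (-1.0 / slope)
    return float(slope), r_squared, float(efficiency)


def percent_input(assay: QpcrAssay, assayed_ip_fraction: float = 0.90) -> float:
    """Percent-of-input recovery from the delta-Ct between input and IP.

    percent = 100 * input_fraction * efficiency**(ct_input - ct_ip)
              / assayed_ip_fraction.  Values above 100% are flagged with a
    warning but reported unclamped.
    """
    if not (0 < assayed_ip_fraction <= 1):
        raise ValueError("assayed_ip_fraction must be in (0, 1]")
    percent = (
        100.0
        * assay.input_fraction
        * assay.efficiency ** (assay.ct_input - assay.ct_ip)
        / assayed_ip_fraction
    )
    if percent > 100.0:
        warnings.warn(f"{assay.target}: percent of input {percent:.1f}% exceeds 100%")
    return percent


def profile_stats(
    profiles: Sequence[GradientProfile],
) -> tuple[list[ProfileStats], dict[tuple[str, str], int]]:
    """Normalize profiles to unit sum, find peaks, and pairwise peak shifts.

    shift(a, b) = peak_b - peak_a in fraction units.
    """
    stats_out = []
    for p in profiles:
        total = float(p.intensities.sum())
        normalized = p.intensities / total
        peak = int(np.argmax(p.intensities)) + 1  # argmax takes the lowest tied index
        stats_out.append(ProfileStats(label=p.label, normalized=normalized, peak_fraction=peak))
    shifts: dict[tuple[str, str], int] = {}
    for a in stats_out:
        for b in stats_out:
            if a.label != b.label:
                shifts[(a.label, b.label)] = b.peak_fraction - a.peak_fraction
    return stats_out, shifts
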