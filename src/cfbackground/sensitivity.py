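"""Spike-in dilution-series sensitivity and binomial detection limits.

Detection rule
--------------
At a candidate site with depth ``n`` and alternate count ``k``, the null is
that all alternate reads are sequencing error: ``K ~ Binomial(n, e/3)`` where
``e`` is the per-base total miscall rate and the uniform-spectrum factor 1/3
routes errors to the specific alternate.  The site is *detected* when the
one-sided exact binomial p-value ``P(K >= k)`` falls below ``alpha`` **and**
``k`` reaches a minimum alternate-read floor (default 3), which prevents
single-error detections at extreme depth.

The limit of detection (LOD) is the smallest true allele fraction ``f`` on a
fixed grid for which the probability of detection reaches the requested
power, with the alternate count distributed ``Binomial(n, f)``: error inflow
to the alternate and miscalls away from it are both neglected, so the error
rate enters only through the detection threshold.  This keeps the LOD
conservative and monotone (non-increasing in depth, non-decreasing in error
rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .filtering import PileupColumn
from .panel import HotspotSite

__all__ = [
    "DilutionDesign",
    "DetectionResult",
    "Observation",
    "CellSummary",
    "SensitivityReport",
    "detect_variant",
    "summarize_series",
    "limit_of_detection",
]


@dataclass(frozen=True)
class DilutionDesign:
    """A spike-in dilution experiment: variants x nominal AF levels x replicates."""

    variants: tuple[HotspotSite, ...]
    levels: tuple[float, ...] = (0.0005, 0.001, 0.005, 0.01)
    replicates: int = 5
    depth: int = 30000

    def __post_init__(self) -> None:
        if any(not 0.0 < lv < 1.0 for lv in self.levels):
            raise ValueError("dilution levels must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.depth < 1:
            raise ValueError("depth must be positive")


@dataclass(frozen=True)
class DetectionResult:
    detected: bool
    p_value: float
    observed_vaf: float


@dataclass(frozen=True)
class Observation:
    """One replicate measurement of one variant at one nominal level."""

    variant: tuple[str, int, str]  # (contig, position, alt)
    level: float
    replicate: int
    observed_vaf: float
    detected: bool


@dataclass(frozen=True)
class CellSummary:
    mean_vaf: float
    standard_error: float
    detection_rate: float
    n_replicates: int


@dataclass(frozen=True)
class SensitivityReport:
    """Per-(variant, level) summaries plus per-level pooled detection rates."""

    cells: Mapping[tuple[tuple[str, int, str], float], CellSummary]
    level_detection_rate: Mapping[float, float]
    level_mean_vaf: Mapping[float, float] = field(default_factory=dict)
    level_standard_error: Mapping[float, float] = field(default_factory=dict)


def detect_variant(
    column: PileupColumn,
    alt_base: str,
    error_rate: float,
    alpha: float = 0.05,
    min_alt: int = 3,
) -> DetectionResult:
    """Exact one-sided binomial test of the alternate count against error."""
    if alt_base == column.ref_base:
        raise ValueError("alt base equals the reference base")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    depth = column.depth
    if depth <= 0:
        raise ValueError("zero-depth column")
    k = column.counts.get(alt_base, 0)
    p_value = float(stats.binom.sf(k - 1, depth, error_rate / 3.0))
    return DetectionResult(
        detected=bool(p_value < alpha and k >= min_alt),
        p_value=p_value,
        observed_vaf=k / depth,
    )


def summarize_series(
    observations: Sequence[Observation],
    design: DilutionDesign,
) -> SensitivityReport:
    """Means, standard errors (SD/sqrt(r)), and detection rates per cell.

    Missing design cells are simply absent from the report, never imputed.
    Per-level figures pool all variants and replicates at that level.
    """
    by_cell: dict[tuple[tuple[str, int, str], float], list[Observation]] = {}
    for obs in observations:
        by_cell.setdefault((obs.variant, obs.level), []).append(obs)

    cells: dict[tuple[tuple[str, int, str], float], CellSummary] = {}
    for key, group in sorted(by_cell.items()):
        vafs = np.array([o.observed_vaf for o in group], dtype=float)
        se = float(vafs.std(ddof=1) / math.sqrt(len(vafs))) if len(vafs) > 1 else 0.0
        cells[key] = CellSummary(
            mean_vaf=float(vafs.mean()),
            standard_error=se,
            detection_rate=sum(o.detected for o in group) / len(group),
            n_replicates=len(group),
        )

    level_rate: dict[float, float] = {}
    level_mean: dict[float, float] = {}
    level_se: dict[float, float] = {}
    for level in design.levels:
        group = [o for o in observations if o.level == level]
        if not group:
            continue
        vafs = np.array([o.observed_vaf for o in group], dtype=float)
        level_rate[level] = sum(o.detected for o in group) / len(group)
        level_mean[level] = float(vafs.mean())
        level_se[level] = (
            float(vafs.std(ddof=1) / math.sqrt(len(vafs))) if len(vafs) > 1 else 0.0
        )
    return SensitivityReport(
        cells=cells,
        level_detection_rate=level_rate,
        level_mean_vaf=level_mean,
        level_standard_error=level_se,
    )


def _critical_alt_count(depth: int, error_rate: float, alpha: float, min_alt: int) -> int:
    """Smallest k >= min_alt whose one-sided p-value under error falls below alpha."""
    k = min_alt
    while k <= depth:
        if stats.binom.sf(k - 1, depth, error_rate / 3.0) < alpha:
            return k
        k += 1
    return depth + 1  # detection impossible


def limit_of_detection(
    depth: int,
    error_rate: float,
    alpha: float = 0.05,
    power: float = 0.95,
    min_alt: int = 3,
    grid_step: float = 1e-5,
    grid_max: float = 0.05,
) -> float:
    """Smallest true VAF detectable with the stated power at this depth.

    Scans a fixed grid of true fractions (``grid_step`` spacing) and returns
    the first whose detection probability under the rule of
    :func:`detect_variant` reaches ``power``.  Non-increasing in depth and
    non-decreasing in error rate.  Raises if even ``grid_max`` is
    insufficient.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    k_crit = _critical_alt_count(depth, error_rate, alpha, min_alt)
    if k_crit > depth:
        raise ValueError(f"no alternate count up to depth {depth} reaches alpha={alpha}")
    grid = np.arange(grid_step, grid_max + grid_step / 2, grid_step)
    detection_power = stats.binom.sf(k_crit - 1, depth, grid)
    hits = np.nonzero(detection_power >= power)[0]
    if hits.size == 0:
        raise ValueError(
            f"power {power} unreachable at depth {depth} within the grid "
            f"(max true VAF {grid_max})"
        )
    return float(grid[hits[0]])
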