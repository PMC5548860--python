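"""Paired-sample concordance of mutant allele frequencies.

Three entry points mirror the three concordance analyses:

* :func:`cohort_paired_means` — average each position's MAF across a cohort of
  WBC/cfDNA pairs (position included in a pair only when it passes the depth
  and MAF thresholds in *both* members), then correlate position means.
* :func:`individual_paired_vector` + :func:`paired_correlation` — raw
  per-position correlation within one individual.
* :func:`replicate_concordance` — technical-replicate reproducibility.

Inclusion thresholds default to depth > 10000x and MAF > 0.003 (0.3%), strict
in both members of a pair.  The regression is ordinary least squares of y on
x; adjusted R-squared uses the single-predictor formula
1 - (1 - R^2)(n - 1)/(n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .vaf import PositionVAF, SampleProfile

__all__ = [
    "PairedVector",
    "CorrelationResult",
    "position_passes",
    "paired_vector",
    "paired_correlation",
    "cohort_mean_profile",
    "cohort_paired_means",
    "individual_paired_vector",
    "replicate_concordance",
]


@dataclass(frozen=True)
class PairedVector:
    """Matched per-position MAF vectors for two samples (x, y)."""

    labels: tuple[tuple[str, int], ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise ValueError("labels, x and y must have equal length")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class CorrelationResult:
    """OLS summary of y on x: Pearson r, R^2, adjusted R^2, slope, intercept."""

    pearson_r: float
    r_squared: float
    adjusted_r_squared: float
    slope: float
    intercept: float
    n: int


def position_passes(p: PositionVAF, min_depth: int, min_maf: float) -> bool:
    """Strict thresholds: depth larger than min_depth AND MAF larger than min_maf."""
    return p.depth > min_depth and p.maf > min_maf


def paired_vector(
    profile_x: SampleProfile,
    profile_y: SampleProfile,
    min_depth: int = 10000,
    min_maf: float = 0.003,
) -> PairedVector:
    """Positions passing the thresholds in *both* profiles, as matched vectors."""
    index_y = profile_y.index()
    labels, xs, ys = [], [], []
    for px in profile_x.positions:
        py = index_y.get(px.key)
        if py is None:
            continue
        if position_passes(px, min_depth, min_maf) and position_passes(py, min_depth, min_maf):
            labels.append(px.key)
            xs.append(px.maf)
            ys.append(py.maf)
    return PairedVector(labels=tuple(labels), x=tuple(xs), y=tuple(ys))


def paired_correlation(v: PairedVector) -> CorrelationResult:
    """Simple least-squares regression of y on x with Pearson correlation.

    Requires n >= 3 and non-constant x.  Pearson r is symmetric in x and y;
    slope and intercept are direction-dependent (y on x).
    """
    if v.n < 3:
        raise ValueError(f"need at least 3 paired positions, got {v.n}")
    x = np.asarray(v.x, dtype=float)
    y = np.asarray(v.y, dtype=float)
    if np.ptp(x) == 0.0:
        raise ValueError("x is constant; correlation undefined")
    fit = stats.linregress(x, y)
    r2 = fit.rvalue**2
    adj = 1.0 - (1.0 - r2) * (v.n - 1) / (v.n - 2)
    return CorrelationResult(
        pearson_r=float(fit.rvalue),
        r_squared=float(r2),
        adjusted_r_squared=float(adj),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=v.n,
    )


def cohort_mean_profile(
    profiles: Sequence[SampleProfile],
    min_depth: int = 10000,
    min_maf: float = 0.003,
) -> dict[tuple[str, int], float]:
    """Per-position mean MAF over the samples in which the position passes.

    Positions that pass in zero samples are omitted.  Pairing constraints
    (pass in both members of a WBC/cfDNA pair) are the caller's concern; see
    :func:`cohort_paired_means` for the paired version.
    """
    if not profiles:
        raise ValueError("cohort_mean_profile requires at least one profile")
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    for profile in profiles:
        for p in profile.positions:
            if position_passes(p, min_depth, min_maf):
                sums[p.key] = sums.get(p.key, 0.0) + p.maf
                counts[p.key] = counts.get(p.key, 0) + 1
    return {key: sums[key] / counts[key] for key in sums}


def cohort_paired_means(
    pairs: Sequence[tuple[SampleProfile, SampleProfile]],
    min_depth: int = 10000,
    min_maf: float = 0.003,
) -> PairedVector:
    """Average MAF per position across WBC/cfDNA pairs, pair-passing inclusion.

    Each pair is (x profile, y profile), e.g. (WBC, cfDNA).  A position enters
    a pair's average only if it passes the thresholds in both members; a
    position seen in no pair is omitted from the output.
    """
    if not pairs:
        raise ValueError("cohort_paired_means requires at least one pair")
    sums_x: dict[tuple[str, int], float] = {}
    sums_y: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    for profile_x, profile_y in pairs:
        index_y = profile_y.index()
        for px in profile_x.positions:
            py = index_y.get(px.key)
            if py is None:
                continue
            if position_passes(px, min_depth, min_maf) and position_passes(
                py, min_depth, min_maf
            ):
                sums_x[px.key] = sums_x.get(px.key, 0.0) + px.maf
                sums_y[px.key] = sums_y.get(px.key, 0.0) + py.maf
                counts[px.key] = counts.get(px.key, 0) + 1
    keys = sorted(counts)
    return PairedVector(
        labels=tuple(keys),
        x=tuple(sums_x[k] / counts[k] for k in keys),
        y=tuple(sums_y[k] / counts[k] for k in keys),
    )


def individual_paired_vector(
    wbc: SampleProfile,
    cfdna: SampleProfile,
    min_depth: int = 10000,
    min_maf: float = 0.003,
) -> PairedVector:
    """Raw per-position WBC-vs-cfDNA vector for a single individual."""
    return paired_vector(wbc, cfdna, min_depth=min_depth, min_maf=min_maf)


def replicate_concordance(
    rep1: SampleProfile,
    rep2: SampleProfile,
    min_depth: int = 10000,
    min_maf: float = 0.003,
) -> CorrelationResult:
    """Concordance of two technical replicates of the same sample.

    Builds the paired vector from positions passing the thresholds in both
    replicates and regresses rep2 on rep1.  Raises if fewer than 3 positions
    survive.
    """
    v = paired_vector(rep1, rep2, min_depth=min_depth, min_maf=min_maf)
    if v.n < 3:
        raise ValueError(
            f"only {v.n} positions pass thresholds in both replicates (need >= 3)"
        )
    return paired_correlation(v)
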