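"""Read-level and base-level filtering, and pileup construction.

Three filters, with strict inequalities exactly as worded in the protocol:

* reads with per-read mutant fraction **higher than** 5% are deleted
  (a read at exactly 0.05 is retained);
* bases with Phred quality **lower than** 30 are deleted (Q30 is kept);
* loci with depth **less than** 10000x are removed (10000x is kept — the
  depth filter itself lives in :func:`cfbackground.vaf.filter_positions`).

The per-read fraction is computed over all aligned match/mismatch bases
*before* quality masking: being hypermutated is a property of the read, not of
its surviving bases.  Bases paired to a reference ``N`` count toward neither
numerator nor denominator anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from .alignments import AlignedRead
from .panel import PanelDefinition

__all__ = [
    "PileupColumn",
    "FilterConfig",
    "FilterTally",
    "read_mutant_fraction",
    "filter_reads",
    "build_pileup",
]

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PileupColumn:
    """Per-position allele counts over retained, unmasked bases.

    ``depth`` is always the sum of ``counts``: a quality-masked base
    contributes to neither the numerator nor the denominator of any
    downstream frequency.
    """

    contig: str
    position: int  # 0-based
    ref_base: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = {b: c for b, c in self.counts.items() if b not in _BASES or c < 0}
        if bad:
            raise ValueError(f"invalid allele counts {bad} at {self.contig}:{self.position}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def alt_depth(self) -> int:
        return self.depth - self.counts.get(self.ref_base, 0)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the read/base/locus filters (defaults = study protocol)."""

    max_read_mutant_fraction: float = 0.05
    min_base_quality: int = 30
    min_locus_depth: int = 10000

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_read_mutant_fraction <= 1.0:
            raise ValueError("max_read_mutant_fraction must be in [0, 1]")
        if self.min_base_quality < 0 or self.min_locus_depth < 0:
            raise ValueError("quality/depth thresholds must be non-negative")


@dataclass
class FilterTally:
    """Attrition bookkeeping emitted by :func:`filter_reads`."""

    reads_in: int = 0
    reads_removed_mutant_fraction: int = 0
    reads_kept: int = 0
    bases_in: int = 0
    bases_masked_quality: int = 0
    bases_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def read_mutant_fraction(read: AlignedRead) -> float:
    """Fraction of a read's aligned bases that mismatch the reference.

    Pairs whose reference base is ``N`` are excluded from numerator and
    denominator.  A read with zero eligible aligned pairs has no defined
    fraction and raises ``ValueError``.
    """
    n = 0
    mismatches = 0
    for pair in read.aligned_pairs:
        if pair.ref_base == "N":
            continue
        n += 1
        if pair.query_base != pair.ref_base:
            mismatches += 1
    if n == 0:
        raise ValueError(f"read {read.query_name}: no aligned pairs with known reference base")
    return mismatches / n


def filter_reads(
    reads: Iterable[AlignedRead],
    config: FilterConfig = FilterConfig(),
    tally: FilterTally | None = None,
) -> Iterator[AlignedRead]:
    """Drop hypermutated reads; mask low-quality bases in the survivors.

    The per-read fraction is evaluated on the unmasked read.  Surviving reads
    are re-emitted with aligned pairs below ``min_base_quality`` removed, so a
    masked base is invisible to pileup construction.  Reads whose pairs all
    mask away are still emitted (they simply contribute nothing).
    """
    own_tally = tally if tally is not None else FilterTally()
    for read in reads:
        own_tally.reads_in += 1
        own_tally.bases_in += len(read.aligned_pairs)
        if read.aligned_pairs and read_mutant_fraction(read) > config.max_read_mutant_fraction:
            own_tally.reads_removed_mutant_fraction += 1
            continue
        kept_pairs = [p for p in read.aligned_pairs if p.base_quality >= config.min_base_quality]
        own_tally.reads_kept += 1
        own_tally.bases_masked_quality += len(read.aligned_pairs) - len(kept_pairs)
        own_tally.bases_kept += len(kept_pairs)
        yield replace(read, aligned_pairs=kept_pairs)
    logger.info("filter_reads tally: %s", own_tally.as_dict())


def build_pileup(
    reads: Iterable[AlignedRead],
    panel: PanelDefinition,
    reference: Mapping[str, str],
) -> list[PileupColumn]:
    """Tally retained bases into per-position columns over panel positions.

    Only positions inside a panel amplicon with at least one retained base
    produce a column; ambiguous query bases (``N``) and pairs at reference
    ``N`` positions are ignored.  Output is sorted by (contig, position) and
    independent of read order.
    """
    counts: dict[tuple[str, int], dict[str, int]] = {}
    amp_index: dict[str, list[tuple[int, int]]] = {}
    for amp in panel.amplicons:
        amp_index.setdefault(amp.contig, []).append((amp.start, amp.end))

    def in_panel(contig: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in amp_index.get(contig, ()))

    for read in reads:
        for pair in read.aligned_pairs:
            if pair.ref_base == "N" or pair.query_base not in _BASES:
                continue
            if not in_panel(read.contig, pair.ref_position):
                continue
            ref_seq = reference.get(read.contig)
            if ref_seq is None or pair.ref_position >= len(ref_seq):
                raise KeyError(
                    f"reference base missing for {read.contig}:{pair.ref_position}"
                )
            site = counts.setdefault((read.contig, pair.ref_position), dict.fromkeys(_BASES, 0))
            site[pair.query_base] += 1

    columns = []
    for (contig, pos) in sorted(counts):
        site = counts[(contig, pos)]
        columns.append(
            PileupColumn(
                contig=contig,
                position=pos,
                ref_base=reference[contig][pos],
                counts={b: c for b, c in site.items() if c > 0},
            )
        )
    return columns
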