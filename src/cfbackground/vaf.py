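"""Per-position mutant allele frequencies and per-gene aggregation.

The mutant allele frequency (MAF) of a position is the total non-reference
fraction of its retained bases: with reference A and counts
A:9990 / C:3 / G:5 / T:2 at depth 10000, the MAF is (3+5+2)/10000 = 0.001.
Per-alternate fractions are kept alongside for hotspot calling.

The per-gene statistic is the arithmetic mean of per-position MAFs over the
gene's amplicon positions:

    F_gene = (F_1 + F_2 + ... + F_n) / n,   n = total amplicon length (bp).

By default the denominator is the full amplicon length — a panel position
with no surviving pileup column contributes 0 to the numerator while still
counting in n.  ``covered_only=True`` divides by the number of surviving
positions instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .filtering import PileupColumn
from .panel import PanelDefinition

__all__ = [
    "PositionVAF",
    "GeneFrequency",
    "SampleProfile",
    "position_vaf",
    "profile_from_pileup",
    "filter_positions",
    "gene_frequency",
    "rank_genes",
    "write_profile",
    "read_profile",
]

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class PositionVAF:
    """Total and per-alternate mutant allele fractions at one position."""

    contig: str
    position: int
    ref_base: str
    depth: int
    maf: float
    per_allele: Mapping[str, float]

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig, self.position)


@dataclass(frozen=True)
class GeneFrequency:
    """Mean per-position MAF of a gene (``n_positions`` = denominator used)."""

    gene: str
    n_positions: int
    f_gene: float


@dataclass
class SampleProfile:
    """One sample's per-position MAF profile (cfDNA, WBC, or tumor)."""

    sample_id: str
    material: str  # "cfDNA" | "WBC" | "tumor"
    positions: list[PositionVAF] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.material not in {"cfDNA", "WBC", "tumor"}:
            raise ValueError(f"unknown material {self.material!r}")
        self.positions = sorted(self.positions, key=lambda p: p.key)
        keys = [p.key for p in self.positions]
        if len(set(keys)) != len(keys):
            raise ValueError(f"sample {self.sample_id}: duplicate positions in profile")

    @property
    def mean_depth(self) -> float:
        if not self.positions:
            return 0.0
        return sum(p.depth for p in self.positions) / len(self.positions)

    def index(self) -> dict[tuple[str, int], PositionVAF]:
        return {p.key: p for p in self.positions}

    def __len__(self) -> int:
        return len(self.positions)


def position_vaf(column: PileupColumn) -> PositionVAF:
    """Total non-reference fraction and per-alternate fractions of a column."""
    depth = column.depth
    if depth <= 0:
        raise ValueError(f"zero depth at {column.contig}:{column.position}")
    if column.ref_base not in _BASES:
        raise ValueError(
            f"ambiguous reference base {column.ref_base!r} at "
            f"{column.contig}:{column.position}"
        )
    alt = {
        b: c / depth
        for b, c in column.counts.items()
        if b != column.ref_base and c > 0
    }
    return PositionVAF(
        contig=column.contig,
        position=column.position,
        ref_base=column.ref_base,
        depth=depth,
        maf=sum(alt.values()),
        per_allele=alt,
    )


def profile_from_pileup(
    columns: Iterable[PileupColumn], sample_id: str, material: str
) -> SampleProfile:
    return SampleProfile(
        sample_id=sample_id,
        material=material,
        positions=[position_vaf(c) for c in columns],
    )


def filter_positions(
    profile: SampleProfile,
    min_depth: int = 10000,
    max_maf: float = 0.1,
) -> SampleProfile:
    """Locus-level filters: depth < ``min_depth`` removed, MAF > ``max_maf``
    removed (germline heterozygous sites near 0.5 fall to the MAF cap).

    Boundaries are kept: depth exactly ``min_depth`` and MAF exactly
    ``max_maf`` survive.  Idempotent.
    """
    kept, low_depth, high_maf = [], 0, 0
    for p in profile.positions:
        if p.depth < min_depth:
            low_depth += 1
        elif p.maf > max_maf:
            high_maf += 1
        else:
            kept.append(p)
    logger.info(
        "filter_positions sample=%s removed_low_depth=%d removed_high_maf=%d kept=%d",
        profile.sample_id, low_depth, high_maf, len(kept),
    )
    return replace(profile, positions=kept)


def gene_frequency(
    profile: SampleProfile,
    panel: PanelDefinition,
    gene: str,
    covered_only: bool = False,
) -> GeneFrequency:
    """Mean per-position MAF over the gene's amplicon positions."""
    amplicons = panel.amplicons_of(gene)  # raises KeyError for unknown gene
    index = profile.index()
    total = 0.0
    covered = 0
    length = 0
    for amp in amplicons:
        length += amp.length
        for pos in range(amp.start, amp.end):
            p = index.get((amp.contig, pos))
            if p is not None:
                total += p.maf
                covered += 1
    n = covered if covered_only else length
    return GeneFrequency(gene=gene, n_positions=n, f_gene=total / n if n else 0.0)


def rank_genes(
    profiles: Sequence[SampleProfile],
    panel: PanelDefinition,
    covered_only: bool = False,
) -> list[tuple[str, float]]:
    """Rank genes by their mean F_gene across samples, descending.

    Ties break lexicographically by gene symbol so the order is deterministic.
    """
    if not profiles:
        raise ValueError("rank_genes requires at least one profile")
    means = []
    for gene in panel.genes:
        values = [gene_frequency(p, panel, gene, covered_only).f_gene for p in profiles]
        means.append((gene, sum(values) / len(values)))
    return sorted(means, key=lambda item: (-item[1], item[0]))


def write_profile(profile: SampleProfile, path: str | Path) -> None:
    """TSV export: ``contig pos ref depth maf A C G T`` (per-base counts)."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tref\tdepth\tmaf\tA\tC\tG\tT\n")
        for p in profile.positions:
            counts = {b: 0 for b in _BASES}
            for b, frac in p.per_allele.items():
                counts[b] = round(frac * p.depth)
            counts[p.ref_base] = p.depth - sum(counts.values())
            fh.write(
                f"{p.contig}\t{p.position}\t{p.ref_base}\t{p.depth}\t"
                f"{p.maf:.10g}\t{counts['A']}\t{counts['C']}\t{counts['G']}\t{counts['T']}\n"
            )


def read_profile(path: str | Path, sample_id: str, material: str) -> SampleProfile:
    positions = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["contig", "pos", "ref", "depth", "maf"]:
            raise ValueError(f"{path}: unexpected profile header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            counts = {b: int(c) for b, c in zip(_BASES, f[5:9]) if int(c) > 0}
            positions.append(
                position_vaf(
                    PileupColumn(contig=f[0], position=int(f[1]), ref_base=f[2], counts=counts)
                )
            )
    return SampleProfile(sample_id=sample_id, material=material, positions=positions)
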