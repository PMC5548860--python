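"""Hotspot mutation calling, WBC background subtraction, and set comparison.

A hotspot call requires the alternate allele's fraction to exceed 1% and the
site's depth to exceed 5000x (both strict, configurable).  Because most cfDNA
derives from blood cells, a cfDNA (or tumor) call whose site also carries the
alternate in the paired WBC sample is treated as blood background and removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .panel import HotspotSite
from .vaf import SampleProfile

__all__ = [
    "MutationCall",
    "call_hotspots",
    "subtract_wbc_background",
    "shared_mutations",
    "write_calls_tsv",
    "write_calls_vcf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutationCall:
    """One called alternate allele at a hotspot site in one sample."""

    contig: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    vaf: float
    depth: int
    sample_id: str
    material: str
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.vaf <= 0:
            raise ValueError("a call requires vaf > 0")
        if self.alt_base == self.ref_base:
            raise ValueError("alt base equals ref base")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.alt_base)


def call_hotspots(
    profile: SampleProfile,
    hotspots: Sequence[HotspotSite],
    min_vaf: float = 0.01,
    min_depth: int = 5000,
) -> list[MutationCall]:
    """Call hotspot alternates with per-allele VAF > min_vaf at depth > min_depth.

    Thresholds are strict (a site at exactly 1% or exactly 5000x is not
    called).  Hotspots without a profiled position are skipped with a
    warning, not an error.  Output is sorted by (contig, position, alt).
    """
    index = profile.index()
    calls: list[MutationCall] = []
    for site in sorted(hotspots):
        p = index.get((site.contig, site.position))
        if p is None:
            logger.warning(
                "hotspot %s:%d outside profile coverage of sample %s",
                site.contig, site.position, profile.sample_id,
            )
            continue
        alt_fraction = p.per_allele.get(site.alt_base, 0.0)
        if alt_fraction > min_vaf and p.depth > min_depth:
            calls.append(
                MutationCall(
                    contig=site.contig,
                    position=site.position,
                    ref_base=site.ref_base,
                    alt_base=site.alt_base,
                    vaf=alt_fraction,
                    depth=p.depth,
                    sample_id=profile.sample_id,
                    material=profile.material,
                )
            )
    calls.sort(key=lambda c: c.key)
    return calls


def subtract_wbc_background(
    cf_calls: Sequence[MutationCall],
    wbc_profile: SampleProfile,
    wbc_max_vaf: float = 0.01,
) -> list[MutationCall]:
    """Remove calls whose site carries the alternate above ``wbc_max_vaf`` in WBC.

    Calls at sites the WBC profile does not cover are retained but flagged
    ``wbc_uncovered``.  With ``wbc_max_vaf=1.0`` this is the identity; with
    ``wbc_max_vaf=0`` any WBC-covered site with a single alternate read is
    removed.
    """
    index = wbc_profile.index()
    kept: list[MutationCall] = []
    removed: list[MutationCall] = []
    for call in cf_calls:
        p = index.get((call.contig, call.position))
        if p is None:
            kept.append(
                MutationCall(
                    **{**call.__dict__, "flags": call.flags + ("wbc_uncovered",)}
                )
            )
        elif p.per_allele.get(call.alt_base, 0.0) > wbc_max_vaf:
            removed.append(call)
        else:
            kept.append(call)
    if removed:
        logger.info(
            "subtract_wbc_background sample=%s removed=%s",
            wbc_profile.sample_id,
            [f"{c.contig}:{c.position}{c.ref_base}>{c.alt_base}" for c in removed],
        )
    return kept


def shared_mutations(
    calls_a: Sequence[MutationCall],
    calls_b: Sequence[MutationCall],
) -> tuple[list[MutationCall], list[MutationCall], list[MutationCall]]:
    """Partition two call lists by (contig, position, alt) into
    (shared, only-in-a, only-in-b); the shared list carries the a-side calls.

    Duplicate keys within either list are an error — calls are unique per
    site and alternate.
    """
    for name, calls in (("a", calls_a), ("b", calls_b)):
        keys = [c.key for c in calls]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate call keys in list {name}")
    keys_b = {c.key for c in calls_b}
    keys_a = {c.key for c in calls_a}
    shared = [c for c in calls_a if c.key in keys_b]
    only_a = [c for c in calls_a if c.key not in keys_b]
    only_b = [c for c in calls_b if c.key not in keys_a]
    return shared, only_a, only_b


def write_calls_tsv(calls: Iterable[MutationCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tref\talt\tvaf\tdepth\tsample_id\tmaterial\tflags\n")
        for c in calls:
            fh.write(
                f"{c.contig}\t{c.position}\t{c.ref_base}\t{c.alt_base}\t"
                f"{c.vaf:.6g}\t{c.depth}\t{c.sample_id}\t{c.material}\t"
                f"{','.join(c.flags) or '.'}\n"
            )


def write_calls_vcf(calls: Iterable[MutationCall], path: str | Path) -> None:
    """Minimal VCF 4.2 export with AF and DP INFO keys (1-based POS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.key):
            fh.write(
                f"{c.contig}\t{c.position + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\t"
                f"PASS\tAF={c.vaf:.6g};DP={c.depth}\n"
            )
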