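"""Aligned-read access: SAM/BAM iteration restricted to the panel.

Alignment itself (BWA upstream in the intended workflow) is out of scope; this
module consumes already-aligned reads.  Only match/mismatch alignment columns
are represented — insertions, deletions and soft-clipped bases never enter the
per-read mutant fraction or the pileup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam

from .panel import PanelDefinition

__all__ = ["AlignedPair", "AlignedRead", "read_alignments", "write_sam"]


@dataclass(frozen=True)
class AlignedPair:
    """One match/mismatch alignment column of a read."""

    query_base: str
    base_quality: int
    ref_position: int
    ref_base: str


@dataclass
class AlignedRead:
    """A read's aligned match/mismatch columns on one contig.

    ``aligned_pairs`` hold only alignment-match columns (CIGAR M/=/X); clipped
    bases and indels are excluded, and ref positions are strictly increasing.
    """

    query_name: str
    contig: str
    ref_start: int
    aligned_pairs: list[AlignedPair] = field(default_factory=list)
    is_unmapped: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        positions = [p.ref_position for p in self.aligned_pairs]
        if any(b >= a for a, b in zip(positions[1:], positions)):
            raise ValueError(f"read {self.query_name}: ref positions not strictly increasing")

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned span (= ref_start if empty)."""
        if not self.aligned_pairs:
            return self.ref_start
        return self.aligned_pairs[-1].ref_position + 1


def read_alignments(
    path: str | Path,
    panel: PanelDefinition,
    reference: Mapping[str, str],
    skip_duplicates: bool = True,
) -> Iterator[AlignedRead]:
    """Stream panel-overlapping reads from a SAM/BAM file.

    Unmapped reads are always skipped; duplicate-flagged reads are skipped by
    default.  Reads whose aligned span does not intersect any panel amplicon
    are dropped.  Soft clips and indels are excluded from ``aligned_pairs``
    (``matches_only`` CIGAR walk).

    Raises ``FileNotFoundError`` for a missing file and ``KeyError`` when a
    read's contig is absent from *reference*.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped:
                continue
            if skip_duplicates and rec.is_duplicate:
                continue
            contig = rec.reference_name
            if contig not in reference:
                raise KeyError(f"contig {contig!r} absent from reference")
            start, end = rec.reference_start, rec.reference_end
            if not any(a.overlaps(contig, start, end) for a in panel.amplicons):
                continue
            seq = rec.query_sequence
            quals = rec.query_qualities
            ref_seq = reference[contig]
            pairs = [
                AlignedPair(seq[qpos], int(quals[qpos]), rpos, ref_seq[rpos])
                for qpos, rpos in rec.get_aligned_pairs(matches_only=True)
            ]
            yield AlignedRead(
                query_name=rec.query_name,
                contig=contig,
                ref_start=start,
                aligned_pairs=pairs,
                is_duplicate=rec.is_duplicate,
            )


def write_sam(
    reads: Iterable[AlignedRead],
    reference: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write reads as plain-text SAM (fully-matching CIGAR per aligned block).

    Intended for synthetic data with contiguous aligned pairs; a read with a
    gap in its ref positions is rejected.
    """
    contigs = list(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(reference[c])} for c in contigs],
    }
    tid = {c: i for i, c in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            pairs = read.aligned_pairs
            if not pairs:
                continue
            positions = [p.ref_position for p in pairs]
            if positions != list(range(positions[0], positions[0] + len(pairs))):
                raise ValueError(f"read {read.query_name}: non-contiguous aligned pairs")
            rec = pysam.AlignedSegment()
            rec.query_name = read.query_name
            rec.reference_id = tid[read.contig]
            rec.reference_start = positions[0]
            rec.query_sequence = "".join(p.query_base for p in pairs)
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(p.base_quality + 33) for p in pairs)
            )
            rec.cigarstring = f"{len(pairs)}M"
            rec.mapping_quality = 60
            rec.flag = 1024 if read.is_duplicate else 0
            out.write(rec)
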