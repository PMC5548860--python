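"""Pileup text I/O in the samtools mpileup 6-column dialect.

Internal coordinates are 0-based half-open; mpileup positions are 1-based.
The conversion happens here and only here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, Sequence

from .filtering import PileupColumn

__all__ = ["write_pileup", "read_pileup"]

_BASES = "ACGT"


def write_pileup(columns: Sequence[PileupColumn], path: str | Path) -> None:
    """Write columns as mpileup text (1-based positions, no header).

    Input must be sorted by (contig, position).  Matches to the reference are
    encoded as ``.`` and mismatches as the uppercase alternate base; base
    qualities are not tracked at the column level and are written as ``I``
    placeholders.  ``read_pileup`` recovers the counts exactly.
    """
    keys = [(c.contig, c.position) for c in columns]
    if keys != sorted(keys):
        raise ValueError("pileup columns must be sorted by (contig, position)")
    with open(path, "w") as fh:
        for col in columns:
            parts = []
            for base, count in sorted(col.counts.items()):
                symbol = "." if base == col.ref_base else base
                parts.append(symbol * count)
            bases = "".join(parts)
            fh.write(
                f"{col.contig}\t{col.position + 1}\t{col.ref_base}\t"
                f"{col.depth}\t{bases}\t{'I' * col.depth}\n"
            )


def read_pileup(path: str | Path) -> list[PileupColumn]:
    """Parse mpileup text back into 0-based :class:`PileupColumn` objects.

    Understands the common mpileup base-string escapes: ``^X`` (read start
    with mapping quality), ``$`` (read end), ``*``/``#`` (deletion
    placeholder), and ``+N.../-N...`` indel insertions, all of which are
    skipped — only match/mismatch observations become allele counts.
    """
    columns: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 mpileup columns")
            contig, pos1, ref = fields[0], int(fields[1]), fields[2].upper()
            counts = dict.fromkeys(_BASES, 0)
            for base in _iter_base_string(fields[4]):
                if base in ".,":
                    if ref in _BASES:
                        counts[ref] += 1
                else:
                    base = base.upper()
                    if base in _BASES:
                        counts[base] += 1
            columns.append(
                PileupColumn(
                    contig=contig,
                    position=pos1 - 1,
                    ref_base=ref,
                    counts={b: c for b, c in counts.items() if c > 0},
                )
            )
    return columns


def _iter_base_string(bases: str) -> Iterator[str]:
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2  # caret plus mapping-quality char
        elif ch == "$":
            i += 1
        elif ch in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num or 0)
        elif ch in "*#":
            i += 1
        else:
            yield ch
            i += 1
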