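"""Targeted-panel definition, hotspot list, and reference-sequence I/O.

The panel is a set of PCR amplicons grouped by gene, together with a list of
pre-specified hotspot sites (position, ref, alt).  All internal coordinates are
0-based half-open; the 1-based convention of the mpileup text dialect is
converted at the I/O boundary only (see :mod:`cfbackground.pileupio`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Amplicon",
    "HotspotSite",
    "PanelDefinition",
    "PanelParseError",
    "load_panel",
    "load_hotspots",
    "load_reference",
    "write_reference",
    "write_panel",
    "write_hotspots",
    "replica_panel_path",
    "replica_hotspots_path",
    "replica_reference_path",
    "load_replica_panel",
]

_VALID_BASES = frozenset("ACGT")


class PanelParseError(ValueError):
    """A panel/hotspot file row that cannot be parsed or validated."""


@dataclass(frozen=True, order=True)
class Amplicon:
    """One PCR-amplified interval of the panel (0-based half-open)."""

    contig: str
    start: int
    end: int
    gene: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise PanelParseError(
                f"invalid amplicon interval [{self.start}, {self.end}) "
                f"for gene {self.gene}: require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        return self.contig == contig and self.start < end and start < self.end


@dataclass(frozen=True, order=True)
class HotspotSite:
    """A pre-specified variant site (0-based position, single-base ref/alt)."""

    contig: str
    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in _VALID_BASES or self.alt_base not in _VALID_BASES:
            raise PanelParseError(
                f"hotspot bases must be A/C/G/T, got {self.ref_base}>{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise PanelParseError(
                f"hotspot at {self.contig}:{self.position} has ref == alt "
                f"({self.ref_base})"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.position, self.alt_base)


@dataclass
class PanelDefinition:
    """The targeted panel: genes, merged amplicons, and hotspot sites.

    Amplicons are merged per (gene, contig) at construction so that, within a
    gene, intervals are non-overlapping and sorted; the covered length is then
    a deterministic sum of amplicon lengths.
    """

    genes: list[str]
    amplicons: list[Amplicon]
    hotspots: list[HotspotSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for amp in self.amplicons:
            if amp.gene not in gene_set:
                raise PanelParseError(
                    f"amplicon on {amp.contig} references unknown gene {amp.gene}"
                )
        self.amplicons = _merge_amplicons(self.amplicons)
        for site in self.hotspots:
            if not any(
                a.overlaps(site.contig, site.position, site.position + 1)
                for a in self.amplicons
            ):
                raise PanelParseError(
                    f"hotspot {site.contig}:{site.position} falls outside "
                    "every amplicon"
                )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicons)

    @property
    def total_bp(self) -> int:
        """Total covered length in bp (amplicons are non-overlapping)."""
        return sum(a.length for a in self.amplicons)

    def amplicons_of(self, gene: str) -> list[Amplicon]:
        if gene not in set(self.genes):
            raise KeyError(f"gene {gene!r} not in panel")
        return [a for a in self.amplicons if a.gene == gene]

    def gene_length(self, gene: str) -> int:
        return sum(a.length for a in self.amplicons_of(gene))

    def positions(self) -> Iterable[tuple[str, int, str]]:
        """Yield (contig, position, gene) over all covered positions, sorted."""
        for amp in self.amplicons:
            for pos in range(amp.start, amp.end):
                yield amp.contig, pos, amp.gene

    def covers(self, contig: str, position: int) -> bool:
        return any(a.overlaps(contig, position, position + 1) for a in self.amplicons)


def _merge_amplicons(amplicons: Iterable[Amplicon]) -> list[Amplicon]:
    """Merge overlapping/adjacent amplicons per (gene, contig); sort globally."""
    by_group: dict[tuple[str, str], list[Amplicon]] = {}
    for amp in amplicons:
        by_group.setdefault((amp.gene, amp.contig), []).append(amp)
    merged: list[Amplicon] = []
    for (gene, contig), group in by_group.items():
        group.sort(key=lambda a: (a.start, a.end))
        cur_start, cur_end = group[0].start, group[0].end
        for amp in group[1:]:
            if amp.start <= cur_end:  # overlap or abut: extend
                cur_end = max(cur_end, amp.end)
            else:
                merged.append(Amplicon(contig, cur_start, cur_end, gene))
                cur_start, cur_end = amp.start, amp.end
        merged.append(Amplicon(contig, cur_start, cur_end, gene))
    merged.sort(key=lambda a: (a.contig, a.start, a.end))
    return merged


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_panel(path: str | Path, hotspots_path: str | Path | None = None) -> PanelDefinition:
    """Load a panel TSV (columns ``gene contig start end``, 0-based half-open).

    Overlapping amplicons of a gene are merged at load time.  If
    *hotspots_path* is given, hotspot sites are loaded and attached.
    """
    path = Path(path)
    amplicons: list[Amplicon] = []
    genes: list[str] = []
    seen_genes: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene", "contig", "start", "end"]
        if header[:4] != expected:
            raise PanelParseError(
                f"{path}:1: expected header {' '.join(expected)}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            gene, contig = fields[0], fields[1]
            try:
                start, end = int(fields[2]), int(fields[3])
            except ValueError as exc:
                raise PanelParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            try:
                amplicons.append(Amplicon(contig, start, end, gene))
            except PanelParseError as exc:
                raise PanelParseError(f"{path}:{lineno}: {exc}") from exc
            if gene not in seen_genes:
                seen_genes.add(gene)
                genes.append(gene)
    hotspots = load_hotspots(hotspots_path) if hotspots_path is not None else []
    return PanelDefinition(genes=genes, amplicons=amplicons, hotspots=hotspots)


def load_hotspots(path: str | Path) -> list[HotspotSite]:
    """Load a hotspot TSV with header ``contig position ref alt`` (0-based)."""
    path = Path(path)
    sites: list[HotspotSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["contig", "position", "ref", "alt"]:
            raise PanelParseError(f"{path}:1: expected header contig position ref alt")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                sites.append(HotspotSite(fields[0], int(fields[1]), fields[2], fields[3]))
            except (ValueError, PanelParseError) as exc:
                raise PanelParseError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcontig\tstart\tend\n")
        for amp in panel.amplicons:
            fh.write(f"{amp.gene}\t{amp.contig}\t{amp.start}\t{amp.end}\n")


def write_hotspots(hotspots: Iterable[HotspotSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tref\talt\n")
        for site in hotspots:
            fh.write(f"{site.contig}\t{site.position}\t{site.ref_base}\t{site.alt_base}\n")


def load_reference(path: str | Path) -> dict[str, str]:
    """Load a FASTA into ``{contig: uppercase sequence}``.

    Ambiguous (non-ACGT) bases are allowed but the contig is flagged via a
    warning; duplicate contig names and empty files are errors.
    """
    import warnings

    path = Path(path)
    sequences: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if name is None:
            return
        seq = "".join(chunks).upper()
        if name in sequences:
            raise ValueError(f"duplicate contig name {name!r} in {path}")
        if set(seq) - _VALID_BASES:
            warnings.warn(f"contig {name!r} contains ambiguous bases", stacklevel=3)
        sequences[name] = seq

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0]
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
    _flush()
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return sequences


def write_reference(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Packaged replica panel (synthetic stand-in with the study's cardinalities)
# ---------------------------------------------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("cfbackground").joinpath("data", name)))


def replica_panel_path() -> Path:
    """Path of the packaged synthetic replica panel TSV (50 genes, 207 amplicons)."""
    return _data_path("replica_panel.tsv")


def replica_hotspots_path() -> Path:
    return _data_path("replica_hotspots.tsv")


def replica_reference_path() -> Path:
    return _data_path("replica_reference.fa")


def load_replica_panel() -> PanelDefinition:
    """Load the packaged replica panel with its 2800 hotspot sites attached.

    The replica panel is a synthetic stand-in that reproduces the study
    panel's cardinalities (50 genes, 207 amplicons, 22027 covered bp, 2800
    hotspots) on a synthetic reference; the real hg19 primer coordinates were
    never published.
    """
    return load_panel(replica_panel_path(), replica_hotspots_path())
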