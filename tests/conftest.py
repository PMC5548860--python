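"""Shared fixtures: the packaged replica panel and small hand-built panels."""

from __future__ import annotations

import numpy as np
import pytest

from cfbackground.alignments import AlignedPair, AlignedRead
from cfbackground.panel import (
    Amplicon,
    PanelDefinition,
    load_reference,
    load_replica_panel,
    replica_reference_path,
)


@pytest.fixture(scope="session")
def replica_panel() -> PanelDefinition:
    return load_replica_panel()


@pytest.fixture(scope="session")
def replica_reference() -> dict[str, str]:
    return load_reference(replica_reference_path())


@pytest.fixture(scope="session")
def tiny_reference() -> dict[str, str]:
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    return {
        "GENE1": "".join(rng.choice(bases, size=300)),
        "GENE2": "".join(rng.choice(bases, size=300)),
    }


@pytest.fixture(scope="session")
def tiny_panel() -> PanelDefinition:
    return PanelDefinition(
        genes=["GENE1", "GENE2"],
        amplicons=[
            Amplicon("GENE1", 20, 120, "GENE1"),
            Amplicon("GENE1", 150, 250, "GENE1"),
            Amplicon("GENE2", 50, 150, "GENE2"),
        ],
    )


def make_read(
    reference: dict[str, str],
    contig: str,
    start: int,
    length: int,
    mismatches: dict[int, str] | None = None,
    quality: int = 35,
    qualities: list[int] | None = None,
    name: str = "read",
) -> AlignedRead:
    """Build a read matching the reference except at *mismatches* (offset → base)."""
    mismatches = mismatches or {}
    seq = reference[contig]
    pairs = []
    for offset in range(length):
        pos = start + offset
        ref = seq[pos]
        base = mismatches.get(offset, ref)
        q = qualities[offset] if qualities is not None else quality
        pairs.append(AlignedPair(base, q, pos, ref))
    return AlignedRead(query_name=name, contig=contig, ref_start=start, aligned_pairs=pairs)
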