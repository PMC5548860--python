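"""Read/base filters and pileup construction, against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfbackground.alignments import AlignedPair, AlignedRead
from cfbackground.filtering import (
    FilterConfig,
    FilterTally,
    build_pileup,
    filter_reads,
    read_mutant_fraction,
)
from cfbackground.panel import Amplicon, PanelDefinition
from tests.conftest import make_read


def naive_filtered_pileup(reads, panel, reference, config):
    """Independent double-loop reimplementation of filter_reads + build_pileup."""
    counts = {}
    for read in reads:
        eligible = [p for p in read.aligned_pairs if p.ref_base != "N"]
        if eligible:
            fraction = sum(p.query_base != p.ref_base for p in eligible) / len(eligible)
            if fraction > config.max_read_mutant_fraction:
                continue
        for pair in read.aligned_pairs:
            if pair.base_quality < config.min_base_quality:
                continue
            if pair.ref_base == "N" or pair.query_base not in "ACGT":
                continue
            covered = False
            for amp in panel.amplicons:
                if amp.contig == read.contig and amp.start <= pair.ref_position < amp.end:
                    covered = True
            if not covered:
                continue
            key = (read.contig, pair.ref_position)
            counts.setdefault(key, {})
            counts[key][pair.query_base] = counts[key].get(pair.query_base, 0) + 1
    return counts


def as_dict(columns):
    return {(c.contig, c.position): dict(c.counts) for c in columns}


class TestReadMutantFraction:
    def test_perfect_read_zero(self, tiny_reference):
        read = make_read(tiny_reference, "GENE1", 20, 100)
        assert read_mutant_fraction(read) == 0.0

    def test_five_percent_boundary_retained(self, tiny_reference):
        seq = tiny_reference["GENE1"]
        mism = {}
        for offset in range(100):
            if len(mism) == 5:
                break
            alt = "A" if seq[20 + offset] != "A" else "C"
            mism[offset] = alt
        read = make_read(tiny_reference, "GENE1", 20, 100, mism)
        assert read_mutant_fraction(read) == pytest.approx(0.05)
        config = FilterConfig()
        assert list(filter_reads([read], config))  # exactly 5% survives

    def test_six_percent_discarded(self, tiny_reference):
        seq = tiny_reference["GENE1"]
        mism = {}
        offset = 0
        while len(mism) < 6:
            alt = "A" if seq[20 + offset] != "A" else "C"
            mism[offset] = alt
            offset += 1
        read = make_read(tiny_reference, "GENE1", 20, 100, mism)
        # brute-force mismatch count over the aligned pairs
        brute = sum(p.query_base != p.ref_base for p in read.aligned_pairs) / 100
        assert read_mutant_fraction(read) == pytest.approx(brute) == pytest.approx(0.06)
        assert not list(filter_reads([read], FilterConfig()))

    def test_reference_n_excluded_both_sides(self):
        pairs = [
            AlignedPair("A", 35, 0, "N"),  # mismatch vs N: ignored
            AlignedPair("C", 35, 1, "C"),
            AlignedPair("G", 35, 2, "C"),
        ]
        read = AlignedRead("r", "c", 0, pairs)
        assert read_mutant_fraction(read) == pytest.approx(0.5)

    def test_empty_read_errors(self):
        read = AlignedRead("r", "c", 0, [])
        with pytest.raises(ValueError, match="no aligned pairs"):
            read_mutant_fraction(read)


class TestBaseQualityMasking:
    def test_q29_masked_but_read_survives(self, tiny_reference, tiny_panel):
        read = make_read(tiny_reference, "GENE1", 30, 50, quality=29)
        (survivor,) = filter_reads([read], FilterConfig())
        assert survivor.aligned_pairs == []
        assert build_pileup([survivor], tiny_panel, tiny_reference) == []

    def test_q30_kept(self, tiny_reference):
        read = make_read(tiny_reference, "GENE1", 30, 50, quality=30)
        (survivor,) = filter_reads([read], FilterConfig())
        assert len(survivor.aligned_pairs) == 50

    def test_fraction_computed_before_masking(self, tiny_reference):
        # hypermutated read whose mismatching bases are all low-quality:
        # still removed, because the fraction is a property of the read
        seq = tiny_reference["GENE1"]
        mism, quals = {}, [35] * 50
        offset = 0
        while len(mism) < 10:
            mism[offset] = "A" if seq[30 + offset] != "A" else "C"
            quals[offset] = 10
            offset += 1
        read = make_read(tiny_reference, "GENE1", 30, 50, mism, qualities=quals)
        assert not list(filter_reads([read], FilterConfig()))

    def test_tally_reconciles(self, tiny_reference):
        reads = [make_read(tiny_reference, "GENE1", 30, 50, name=f"r{i}") for i in range(4)]
        tally = FilterTally()
        list(filter_reads(reads, FilterConfig(), tally))
        assert tally.reads_in == tally.reads_kept + tally.reads_removed_mutant_fraction
        assert tally.bases_in == tally.bases_kept + tally.bases_masked_quality


class TestBuildPileup:
    def test_two_reads_same_base(self, tiny_reference, tiny_panel):
        reads = [make_read(tiny_reference, "GENE1", 50, 1, name=f"r{i}") for i in range(2)]
        (column,) = build_pileup(reads, tiny_panel, tiny_reference)
        ref = tiny_reference["GENE1"][50]
        assert dict(column.counts) == {ref: 2}
        assert column.depth == 2

    def test_counts_equal_hand_tally(self, tiny_reference, tiny_panel):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(10):
            base = str(rng.choice(list("ACGT")))
            reads.append(
                make_read(tiny_reference, "GENE1", 60, 1, mismatches={0: base}, name=f"r{i}")
            )
        (column,) = build_pileup(reads, tiny_panel, tiny_reference)
        hand = {}
        for read in reads:
            b = read.aligned_pairs[0].query_base
            hand[b] = hand.get(b, 0) + 1
        assert dict(column.counts) == hand

    def test_conservation_depth_equals_count_sum(self, tiny_reference, tiny_panel):
        reads = [
            make_read(tiny_reference, "GENE1", 40, 60, name=f"r{i}") for i in range(5)
        ]
        for column in build_pileup(reads, tiny_panel, tiny_reference):
            assert column.depth == sum(column.counts.values())


class TestOracleEquivalence:
    def _random_instance(self, seed, tiny_reference, max_reads=300):
        rng = np.random.default_rng(seed)
        reads = []
        n = int(rng.integers(1, max_reads))
        for i in range(n):
            contig = "GENE1" if rng.random() < 0.5 else "GENE2"
            length = int(rng.integers(20, 100))
            start = int(rng.integers(0, 300 - length))
            n_mism = int(rng.integers(0, max(2, length // 10)))
            offsets = rng.choice(length, size=min(n_mism, length), replace=False)
            seq = tiny_reference[contig]
            mism = {}
            for off in offsets:
                ref = seq[start + int(off)]
                mism[int(off)] = str(rng.choice([b for b in "ACGT" if b != ref]))
            quals = rng.integers(10, 42, size=length).tolist()
            reads.append(
                make_read(
                    tiny_reference, contig, start, length, mism,
                    qualities=quals, name=f"r{seed}_{i}",
                )
            )
        return reads

    def test_matches_naive_double_loop(self, tiny_reference, tiny_panel):
        config = FilterConfig()
        for seed in range(30):
            reads = self._random_instance(seed, tiny_reference)
            fast = as_dict(
                build_pileup(filter_reads(reads, config), tiny_panel, tiny_reference)
            )
            slow = naive_filtered_pileup(reads, tiny_panel, tiny_reference, config)
            assert fast == slow, f"seed {seed}"

    def test_order_invariance(self, tiny_reference, tiny_panel):
        reads = self._random_instance(99, tiny_reference, max_reads=100)
        config = FilterConfig()
        forward = as_dict(
            build_pileup(filter_reads(reads, config), tiny_panel, tiny_reference)
        )
        backward = as_dict(
            build_pileup(filter_reads(reads[::-1], config), tiny_panel, tiny_reference)
        )
        assert forward == backward


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    minq=st.integers(min_value=0, max_value=45),
    maxfrac=st.floats(min_value=0.0, max_value=1.0),
)
def test_filter_monotonicity(minq, maxfrac):
    """Raising min quality never raises a count; raising the allowed mutant
    fraction never lowers one."""
    rng = np.random.default_rng(5)
    reference = {"G": "".join(rng.choice(list("ACGT"), size=120))}
    panel = PanelDefinition(genes=["G"], amplicons=[Amplicon("G", 0, 120, "G")])
    reads = []
    for i in range(40):
        length = int(rng.integers(10, 60))
        start = int(rng.integers(0, 120 - length))
        offsets = rng.choice(length, size=int(rng.integers(0, 4)), replace=False)
        seq = reference["G"]
        mism = {
            int(o): str(rng.choice([b for b in "ACGT" if b != seq[start + int(o)]]))
            for o in offsets
        }
        quals = rng.integers(20, 42, size=length).tolist()
        reads.append(make_read(reference, "G", start, length, mism, qualities=quals, name=f"r{i}"))

    def totals(config):
        columns = build_pileup(filter_reads(reads, config), panel, reference)
        return {(c.contig, c.position): dict(c.counts) for c in columns}

    base = totals(FilterConfig(max_read_mutant_fraction=maxfrac, min_base_quality=minq))
    stricter_q = totals(FilterConfig(max_read_mutant_fraction=maxfrac, min_base_quality=minq + 5))
    for key, counts in stricter_q.items():
        for b, c in counts.items():
            assert c <= base[key][b]
    looser_frac = totals(
        FilterConfig(max_read_mutant_fraction=min(1.0, maxfrac + 0.2), min_base_quality=minq)
    )
    for key, counts in base.items():
        for b, c in counts.items():
            assert looser_frac[key][b] >= c
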