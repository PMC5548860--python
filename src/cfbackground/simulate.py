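"""Synthetic data generation for the whole pipeline, with truth tables.

Every generator is a pure function of its seed(s): repeated calls with the
same arguments are identical.  The generative model mirrors the study's
data-generating assumptions:

* a 50-gene, 207-amplicon, 22027 bp panel with 2800 hotspot sites on a
  synthetic reference (one contig per gene);
* per-position *true* somatic background frequencies drawn from an
  exponential law (mass near zero, rare larger clones), with per-gene
  elevation multipliers (an NPM1-like gene elevated x10 by default) and a
  hard cap;
* a cfDNA profile that shares most of its somatic signal with the paired
  WBC profile (``shared_weight``, default 0.9 — most cfDNA derives from
  blood cells) plus an independently drawn minority component;
* germline heterozygous positions at allele fraction 0.5 in both members;
* observed counts that are (beta-)binomial draws at Poisson-distributed
  depth around ``mean_depth`` (default 40000x), with uniform-spectrum
  sequencing error added at ``base_error_rate``;
* spike-in dilution series at nominal fractions 0.0005-0.01 and ~30000x.

Count-level simulation (straight to :class:`SampleProfile`) is the default
and is what the cohort-scale experiments use; read-level simulation (emitting
:class:`AlignedRead`/SAM with per-base Phred qualities) is provided for
exercising the read filters and pileup construction at small scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignments import AlignedPair, AlignedRead
from .filtering import PileupColumn
from .panel import Amplicon, HotspotSite, PanelDefinition
from .sensitivity import DilutionDesign
from .vaf import PositionVAF, SampleProfile

__all__ = [
    "GENE_SYMBOLS",
    "SimulationConfig",
    "TruthTable",
    "SpikeinMeasurement",
    "simulate_reference_and_panel",
    "simulate_pair",
    "simulate_replicates",
    "simulate_trio",
    "simulate_spikein_series",
    "simulate_null_columns",
    "simulate_reads",
]

_BASES = np.array(["A", "C", "G", "T"])

# 50 cancer-associated gene symbols used for the replica panel's loci.
GENE_SYMBOLS = (
    "ABL1", "AKT1", "ALK", "APC", "ATM", "BRAF", "CDH1", "CDKN2A", "CSF1R",
    "CTNNB1", "EGFR", "ERBB2", "ERBB4", "EZH2", "FBXW7", "FGFR1", "FGFR2",
    "FGFR3", "FLT3", "GNA11", "GNAQ", "GNAS", "HNF1A", "HRAS", "IDH1", "IDH2",
    "JAK2", "JAK3", "KDR", "KIT", "KRAS", "MET", "MLH1", "MPL", "NOTCH1",
    "NPM1", "NRAS", "PDGFRA", "PIK3CA", "PTEN", "PTPN11", "RB1", "RET",
    "SMAD4", "SMARCB1", "SMO", "SRC", "STK11", "TP53", "VHL",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort.

    Defaults are the study's conditions: 40000x mean depth, a shared blood
    background carrying 90% of the cfDNA signal, per-base miscall rate 1e-4,
    exponential background with mean 2e-4 per position, one NPM1-like gene
    elevated tenfold, and pure-binomial counts (``overdispersion`` = 0;
    a beta-binomial rho > 0 emulates PCR jackpot noise).
    """

    seed: int = 0
    n_pairs: int = 20
    mean_depth: int = 40000
    base_error_rate: float = 1e-4
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    background_scale: float = 2e-4
    background_cap: float = 0.05
    gene_elevation: Mapping[str, float] = field(
        default_factory=lambda: {"NPM1": 10.0}
    )
    shared_weight: float = 0.9
    germline_het_density: float = 0.001
    overdispersion: float = 0.0
    spikein: DilutionDesign | None = None

    def __post_init__(self) -> None:
        for name in ("base_error_rate", "background_scale", "background_cap",
                     "shared_weight", "germline_het_density", "overdispersion"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")


@dataclass
class TruthTable:
    """Per-(sample, position) ground truth backing every synthetic dataset."""

    entries: pd.DataFrame
    # columns: sample_id, contig, position, ref_base, alt_base,
    #          true_freq, germline, origin, spike_nominal

    def for_sample(self, sample_id: str) -> pd.DataFrame:
        return self.entries[self.entries["sample_id"] == sample_id]

    def true_freq(self, sample_id: str, contig: str, position: int) -> float:
        df = self.entries
        mask = (
            (df["sample_id"] == sample_id)
            & (df["contig"] == contig)
            & (df["position"] == position)
        )
        return float(df.loc[mask, "true_freq"].iloc[0])


# ---------------------------------------------------------------------------
# Reference + panel
# ---------------------------------------------------------------------------

def simulate_reference_and_panel(
    seed: int,
    n_genes: int = 50,
    n_amplicons: int = 207,
    total_bp: int = 22027,
    n_hotspots: int = 2800,
    flank_bp: int = 20,
) -> tuple[dict[str, str], PanelDefinition]:
    """Generate a synthetic reference and panel with the study's cardinalities.

    One contig per gene; amplicon lengths partition ``total_bp`` near-evenly
    (real amplicons cluster around a common size); hotspots are placed
    uniformly over covered positions without replacement, with a random
    alternate base differing from the reference.  Fully deterministic per
    seed.
    """
    if n_amplicons < n_genes:
        raise ValueError("need at least one amplicon per gene")
    if total_bp < n_amplicons:
        raise ValueError(f"cannot partition {total_bp} bp into {n_amplicons} amplicons")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x50A7E1)))

    genes = list(GENE_SYMBOLS[:n_genes])
    if len(genes) < n_genes:
        genes += [f"GENE{i:03d}" for i in range(len(genes), n_genes)]

    # amplicons per gene: one NPM1-like single-amplicon gene, rest random >= 1
    per_gene = np.ones(n_genes, dtype=int)
    single = genes.index("NPM1") if "NPM1" in genes else 0
    spare = n_amplicons - n_genes
    eligible = np.array([i for i in range(n_genes) if i != single])
    if spare > 0:
        extra = rng.multinomial(spare, np.full(len(eligible), 1.0 / len(eligible)))
        per_gene[eligible] += extra

    # near-even length partition (real amplicons cluster around one size)
    base, extra = divmod(total_bp, n_amplicons)
    lengths = np.full(n_amplicons, base, dtype=int)
    lengths[:extra] += 1

    reference: dict[str, str] = {}
    amplicons: list[Amplicon] = []
    cursor = 0
    for gi, gene in enumerate(genes):
        contig = gene
        offset = flank_bp
        spans = []
        for _ in range(per_gene[gi]):
            length = int(lengths[cursor])
            cursor += 1
            spans.append((offset, offset + length))
            offset += length + flank_bp
        seq = "".join(rng.choice(_BASES, size=offset))
        reference[contig] = seq
        for start, end in spans:
            amplicons.append(Amplicon(contig, start, end, gene))

    covered = [
        (a.contig, pos) for a in amplicons for pos in range(a.start, a.end)
    ]
    chosen = rng.choice(len(covered), size=n_hotspots, replace=False)
    hotspots = []
    for idx in sorted(chosen):
        contig, pos = covered[idx]
        ref = reference[contig][pos]
        alts = [b for b in "ACGT" if b != ref]
        hotspots.append(HotspotSite(contig, pos, ref, alts[rng.integers(3)]))

    panel = PanelDefinition(genes=genes, amplicons=amplicons, hotspots=hotspots)
    return reference, panel


# ---------------------------------------------------------------------------
# Truth draws and count draws
# ---------------------------------------------------------------------------

def _panel_arrays(panel: PanelDefinition, reference: Mapping[str, str]):
    contigs, positions, refs, gene_names = [], [], [], []
    for amp in panel.amplicons:
        seq = reference[amp.contig]
        for pos in range(amp.start, amp.end):
            contigs.append(amp.contig)
            positions.append(pos)
            refs.append(seq[pos])
            gene_names.append(amp.gene)
    return (
        np.array(contigs),
        np.array(positions, dtype=int),
        np.array(refs),
        np.array(gene_names),
    )


def _draw_background(rng, config: SimulationConfig, genes: np.ndarray) -> np.ndarray:
    scale = np.full(genes.shape, config.background_scale)
    for gene, mult in config.gene_elevation.items():
        scale[genes == gene] *= mult
    return np.minimum(rng.exponential(scale), config.background_cap)


def _draw_alt_bases(rng, refs: np.ndarray) -> np.ndarray:
    """One designated somatic alternate per position, never the reference."""
    shift = rng.integers(1, 4, size=refs.shape)
    ref_idx = np.searchsorted(_BASES, refs)
    return _BASES[(ref_idx + shift) % 4]


def _draw_counts(
    rng,
    true_freq: np.ndarray,
    config: SimulationConfig,
    depth_mean: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed (depth, somatic alt count, 3 error counts) per position."""
    n = true_freq.shape[0]
    depth = rng.poisson(depth_mean or config.mean_depth, size=n)
    depth = np.maximum(depth, 1)
    rho = config.overdispersion
    if rho > 0.0:
        nu = 1.0 / rho - 1.0
        f = np.clip(true_freq, 1e-12, 1 - 1e-12)
        p = rng.beta(f * nu, (1.0 - f) * nu)
    else:
        p = true_freq
    alt = rng.binomial(depth, p)
    errors = rng.binomial(depth[:, None], config.base_error_rate / 3.0, size=(n, 3))
    return depth, alt, errors


def _profile_from_draws(
    sample_id: str,
    material: str,
    contigs: np.ndarray,
    positions: np.ndarray,
    refs: np.ndarray,
    alts: np.ndarray,
    depth: np.ndarray,
    alt_count: np.ndarray,
    errors: np.ndarray,
) -> SampleProfile:
    """Assemble per-position counts into a profile (Σ counts == depth)."""
    ref_idx = np.searchsorted(_BASES, refs)
    alt_idx = np.searchsorted(_BASES, alts)
    n = contigs.shape[0]
    counts = np.zeros((n, 4), dtype=int)
    counts[np.arange(n), alt_idx] += alt_count
    # route the three error draws to the three non-reference bases
    for j in range(3):
        target = (ref_idx + 1 + j) % 4
        counts[np.arange(n), target] += errors[:, j]
    non_ref = counts.sum(axis=1)
    # somatic + error draws exceeding depth are truncated (vanishingly rare)
    over = non_ref > depth
    if over.any():
        counts[over] = (counts[over] * (depth[over] / non_ref[over])[:, None]).astype(int)
        non_ref = counts.sum(axis=1)
    counts[np.arange(n), ref_idx] += depth - non_ref

    profile_positions = []
    for i in range(n):
        d = int(counts[i].sum())
        ref = refs[i]
        per_allele = {
            str(_BASES[j]): counts[i, j] / d
            for j in range(4)
            if j != ref_idx[i] and counts[i, j] > 0
        }
        profile_positions.append(
            PositionVAF(
                contig=str(contigs[i]),
                position=int(positions[i]),
                ref_base=str(ref),
                depth=d,
                maf=float(sum(per_allele.values())),
                per_allele=per_allele,
            )
        )
    return SampleProfile(sample_id=sample_id, material=material, positions=profile_positions)


def _truth_frame(
    sample_id: str,
    contigs: np.ndarray,
    positions: np.ndarray,
    refs: np.ndarray,
    alts: np.ndarray,
    freqs: np.ndarray,
    germline: np.ndarray,
    origin: str = "background",
    spike_nominal: float = np.nan,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "contig": contigs,
            "position": positions,
            "ref_base": refs,
            "alt_base": alts,
            "true_freq": freqs,
            "germline": germline,
            "origin": origin,
            "spike_nominal": spike_nominal,
        }
    )


# ---------------------------------------------------------------------------
# Paired samples, replicates, trios, spike-ins
# ---------------------------------------------------------------------------

def simulate_pair(
    config: SimulationConfig,
    pair_index: int,
    panel: PanelDefinition,
    reference: Mapping[str, str],
) -> tuple[SampleProfile, SampleProfile, TruthTable]:
    """One WBC/cfDNA pair: shared somatic background plus independent residue.

    WBC true frequencies are exponential (gene-elevated, capped); the cfDNA
    truth is ``shared_weight * wbc + (1 - shared_weight) * independent``.
    Germline heterozygous positions sit at 0.5 in both.  Observed counts are
    (beta-)binomial at Poisson depth with sequencing error on top.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, pair_index)))
    contigs, positions, refs, genes = _panel_arrays(panel, reference)
    wbc_f = _draw_background(rng, config, genes)
    indep_f = _draw_background(rng, config, genes)
    cf_f = config.shared_weight * wbc_f + (1.0 - config.shared_weight) * indep_f
    germline = rng.random(contigs.shape[0]) < config.germline_het_density
    wbc_f = np.where(germline, 0.5, wbc_f)
    cf_f = np.where(germline, 0.5, cf_f)
    alts = _draw_alt_bases(rng, refs)

    wbc_id = f"pair{pair_index:03d}_WBC"
    cf_id = f"pair{pair_index:03d}_cfDNA"
    wbc = _profile_from_draws(
        wbc_id, "WBC", contigs, positions, refs, alts,
        *_draw_counts(rng, wbc_f, config),
    )
    cf = _profile_from_draws(
        cf_id, "cfDNA", contigs, positions, refs, alts,
        *_draw_counts(rng, cf_f, config),
    )
    truth = TruthTable(
        entries=pd.concat(
            [
                _truth_frame(wbc_id, contigs, positions, refs, alts, wbc_f, germline),
                _truth_frame(cf_id, contigs, positions, refs, alts, cf_f, germline),
            ],
            ignore_index=True,
        )
    )
    return wbc, cf, truth


def simulate_replicates(
    config: SimulationConfig,
    panel: PanelDefinition,
    reference: Mapping[str, str],
    material: str = "WBC",
    sample_index: int = 0,
    mean_depth: int | None = None,
    base_error_rate: float | None = None,
) -> tuple[SampleProfile, SampleProfile, TruthTable]:
    """Two technical replicates: independent count draws from one truth table."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2, sample_index)))
    contigs, positions, refs, genes = _panel_arrays(panel, reference)
    true_f = _draw_background(rng, config, genes)
    germline = rng.random(contigs.shape[0]) < config.germline_het_density
    true_f = np.where(germline, 0.5, true_f)
    alts = _draw_alt_bases(rng, refs)

    if base_error_rate is not None:
        config = SimulationConfig(**{**config.__dict__, "base_error_rate": base_error_rate})
    reps = []
    for r in (1, 2):
        reps.append(
            _profile_from_draws(
                f"sample{sample_index:03d}_rep{r}", material,
                contigs, positions, refs, alts,
                *_draw_counts(rng, true_f, config, depth_mean=mean_depth),
            )
        )
    truth = TruthTable(
        entries=_truth_frame(
            f"sample{sample_index:03d}", contigs, positions, refs, alts, true_f, germline
        )
    )
    return reps[0], reps[1], truth


def simulate_trio(
    config: SimulationConfig,
    panel: PanelDefinition,
    reference: Mapping[str, str],
    n_truncal: int = 6,
    n_private_per_section: int = 5,
    n_cf_detectable: int = 3,
    tumor_vaf: float = 0.2,
    cf_leak_vaf: float = 0.02,
    n_shared_background: int = 5,
    background_hotspot_vaf: float = 0.03,
) -> tuple[SampleProfile, SampleProfile, SampleProfile, SampleProfile, TruthTable]:
    """A patient 'trio': WBC, cfDNA, and two tumor sections, hotspot-designed.

    Truncal variants appear in both tumor sections; each section additionally
    carries private variants; ``n_cf_detectable`` truncal variants leak into
    the cfDNA at ``cf_leak_vaf``.  ``n_shared_background`` hotspot sites are
    elevated in the WBC (and hence, via the shared weight, in the cfDNA) so
    that WBC background subtraction has real work to do.  The truth table
    labels every designed variant's origin.
    """
    needed = n_truncal + 2 * n_private_per_section + n_shared_background
    if needed > len(panel.hotspots):
        raise ValueError(f"design needs {needed} hotspots, panel has {len(panel.hotspots)}")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 3)))
    contigs, positions, refs, genes = _panel_arrays(panel, reference)
    key_to_idx = {(c, p): i for i, (c, p) in enumerate(zip(contigs, positions))}

    chosen = rng.choice(len(panel.hotspots), size=needed, replace=False)
    sites = [panel.hotspots[i] for i in chosen]
    truncal = sites[:n_truncal]
    private1 = sites[n_truncal : n_truncal + n_private_per_section]
    private2 = sites[n_truncal + n_private_per_section : n_truncal + 2 * n_private_per_section]
    shared_bg = sites[n_truncal + 2 * n_private_per_section :]
    leaked = truncal[:n_cf_detectable]

    wbc_f = _draw_background(rng, config, genes)
    alts = _draw_alt_bases(rng, refs)

    def _apply(freqs: np.ndarray, variant_sites, vaf: float) -> np.ndarray:
        out = freqs.copy()
        for site in variant_sites:
            out[key_to_idx[(site.contig, site.position)]] = vaf
        return out

    def _pin_alts(variant_sites) -> None:
        for site in variant_sites:
            alts[key_to_idx[(site.contig, site.position)]] = site.alt_base

    for group in (truncal, private1, private2, shared_bg):
        _pin_alts(group)

    wbc_f = _apply(wbc_f, shared_bg, background_hotspot_vaf)
    cf_f = config.shared_weight * wbc_f
    cf_f = _apply(cf_f, leaked, cf_leak_vaf)
    sec1_f = _apply(_apply(np.zeros_like(wbc_f), truncal, tumor_vaf), private1, tumor_vaf)
    sec2_f = _apply(_apply(np.zeros_like(wbc_f), truncal, tumor_vaf), private2, tumor_vaf)

    germline = np.zeros(contigs.shape[0], dtype=bool)
    samples = {
        "trio_WBC": ("WBC", wbc_f),
        "trio_cfDNA": ("cfDNA", cf_f),
        "trio_tumor1": ("tumor", sec1_f),
        "trio_tumor2": ("tumor", sec2_f),
    }
    profiles = {}
    frames = []
    for sample_id, (material, freqs) in samples.items():
        profiles[sample_id] = _profile_from_draws(
            sample_id, material, contigs, positions, refs, alts,
            *_draw_counts(rng, freqs, config),
        )
        frame = _truth_frame(sample_id, contigs, positions, refs, alts, freqs, germline)
        frames.append(frame)
    truth = TruthTable(entries=pd.concat(frames, ignore_index=True))
    origin = np.full(contigs.shape[0], "background", dtype=object)
    for group, label in (
        (truncal, "truncal"),
        (private1, "private1"),
        (private2, "private2"),
        (shared_bg, "shared_background"),
    ):
        for site in group:
            origin[key_to_idx[(site.contig, site.position)]] = label
    for site in leaked:
        origin[key_to_idx[(site.contig, site.position)]] = "truncal_cf_leak"
    truth.entries["origin"] = np.tile(origin, len(samples))
    return (
        profiles["trio_WBC"],
        profiles["trio_cfDNA"],
        profiles["trio_tumor1"],
        profiles["trio_tumor2"],
        truth,
    )


@dataclass(frozen=True)
class SpikeinMeasurement:
    """One simulated replicate of one spike-in variant at one nominal level."""

    variant: HotspotSite
    level: float
    replicate: int
    column: PileupColumn


def simulate_spikein_series(
    design: DilutionDesign,
    config: SimulationConfig,
) -> list[SpikeinMeasurement]:
    """Pileup columns for every (variant, level, replicate) design cell.

    The spiked alternate count is (beta-)binomial at the nominal fraction;
    sequencing error at ``base_error_rate`` (uniform spectrum) is added to
    all non-reference bases.  Depth is Poisson around the design depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 4)))
    out: list[SpikeinMeasurement] = []
    for variant in design.variants:
        ref = variant.ref_base
        others = [b for b in "ACGT" if b != ref]
        for level in design.levels:
            freqs = np.full(design.replicates, level)
            depth, alt, errors = _draw_counts(rng, freqs, config, depth_mean=design.depth)
            for rep in range(1, design.replicates + 1):
                i = rep - 1
                counts = dict.fromkeys("ACGT", 0)
                counts[variant.alt_base] += int(alt[i])
                for j, b in enumerate(others):
                    counts[b] += int(errors[i, j])
                non_ref = sum(counts.values())
                counts[ref] = max(int(depth[i]) - non_ref, 0)
                out.append(
                    SpikeinMeasurement(
                        variant=variant,
                        level=level,
                        replicate=rep,
                        column=PileupColumn(
                            contig=variant.contig,
                            position=variant.position,
                            ref_base=ref,
                            counts={b: c for b, c in counts.items() if c > 0},
                        ),
                    )
                )
    return out


def simulate_null_columns(
    seed: int,
    n: int,
    depth: int,
    error_rate: float,
    ref_base: str = "A",
    alt_base: str = "C",
) -> list[PileupColumn]:
    """Error-only columns (no spike-in): the type-I regime of the detector."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 5)))
    depths = np.maximum(rng.poisson(depth, size=n), 1)
    errors = rng.binomial(depths[:, None], error_rate / 3.0, size=(n, 3))
    others = [b for b in "ACGT" if b != ref_base]
    columns = []
    for i in range(n):
        counts = {ref_base: int(depths[i] - errors[i].sum())}
        for j, b in enumerate(others):
            if errors[i, j] > 0:
                counts[b] = int(errors[i, j])
        columns.append(
            PileupColumn(contig="null", position=i, ref_base=ref_base, counts=counts)
        )
    return columns


# ---------------------------------------------------------------------------
# Read-level simulation (small-scale, for the read filters and pileup)
# ---------------------------------------------------------------------------

def simulate_reads(
    seed: int,
    panel: PanelDefinition,
    reference: Mapping[str, str],
    truth: Mapping[tuple[str, int], tuple[str, float]] | None = None,
    mean_depth: int = 100,
    read_length: int = 160,
    base_error_rate: float = 1e-4,
    quality_mean: float = 36.0,
    quality_sd: float = 3.0,
) -> list[AlignedRead]:
    """Emit single-end fixed-length reads over the panel with Phred qualities.

    *truth* maps (contig, position) to (alt base, true fraction); each read
    base at such a position carries the alternate with that probability.
    Sequencing errors then flip any base to a random other base at
    ``base_error_rate``; qualities are normal draws clipped to [2, 41].
    Read count per amplicon is ``mean_depth * length / read_length``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 6)))
    truth = truth or {}
    reads: list[AlignedRead] = []
    serial = 0
    for amp in panel.amplicons:
        seq = reference[amp.contig]
        length = min(read_length, amp.length)
        n_reads = max(1, round(mean_depth * amp.length / length))
        starts = rng.integers(amp.start, amp.end - length + 1, size=n_reads)
        for start in starts:
            start = int(start)
            quals = np.clip(
                rng.normal(quality_mean, quality_sd, size=length), 2, 41
            ).astype(int)
            pairs = []
            for offset in range(length):
                pos = start + offset
                ref = seq[pos]
                base = ref
                spike = truth.get((amp.contig, pos))
                if spike is not None and rng.random() < spike[1]:
                    base = spike[0]
                if rng.random() < base_error_rate:
                    base = str(rng.choice([b for b in "ACGT" if b != base]))
                pairs.append(AlignedPair(base, int(quals[offset]), pos, ref))
            reads.append(
                AlignedRead(
                    query_name=f"sim{serial:07d}",
                    contig=amp.contig,
                    ref_start=start,
                    aligned_pairs=pairs,
                )
            )
            serial += 1
    return reads
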