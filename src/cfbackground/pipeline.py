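"""End-to-end orchestration: manifest-driven runs with structured reports.

A run manifest is a TSV listing samples (``sample_id material path pair_id
replicate_id``) plus the panel/hotspots/reference paths.  ``run_pipeline``
takes each sample through filtering, pileup, VAF profiling and position
filtering, then performs the paired analyses (per-pair correlation, hotspot
calling with WBC subtraction) and gene ranking.  A failing sample is recorded
in the report without aborting the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignments import read_alignments
from .calling import call_hotspots, subtract_wbc_background
from .filtering import FilterConfig, FilterTally, build_pileup, filter_reads
from .paired import individual_paired_vector, paired_correlation
from .panel import PanelDefinition, load_hotspots, load_panel, load_reference
from .pileupio import read_pileup
from .vaf import SampleProfile, filter_positions, profile_from_pileup, rank_genes

__all__ = ["ManifestSample", "RunManifest", "RunReport", "validate_manifest", "run_pipeline"]

logger = logging.getLogger(__name__)

_MATERIALS = {"cfDNA", "WBC", "tumor"}


@dataclass(frozen=True)
class ManifestSample:
    sample_id: str
    material: str
    path: str
    pair_id: str = ""
    replicate_id: str = ""


@dataclass
class RunManifest:
    samples: list[ManifestSample]
    panel_path: str
    reference_path: str
    hotspots_path: str = ""

    @classmethod
    def from_file(cls, path: str | Path) -> "RunManifest":
        """Parse the manifest TSV; ``#key value`` comment lines set paths."""
        path = Path(path)
        samples: list[ManifestSample] = []
        meta: dict[str, str] = {}
        with open(path) as fh:
            header: list[str] | None = None
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    parts = line[1:].split("\t")
                    if len(parts) == 2:
                        meta[parts[0].strip()] = parts[1].strip()
                    continue
                fields = line.split("\t")
                if header is None:
                    header = fields
                    continue
                row = dict(zip(header, fields))
                samples.append(
                    ManifestSample(
                        sample_id=row.get("sample_id", ""),
                        material=row.get("material", ""),
                        path=row.get("path", ""),
                        pair_id=row.get("pair_id", ""),
                        replicate_id=row.get("replicate_id", ""),
                    )
                )
        return cls(
            samples=samples,
            panel_path=meta.get("panel", ""),
            reference_path=meta.get("reference", ""),
            hotspots_path=meta.get("hotspots", ""),
        )


def validate_manifest(manifest: RunManifest) -> list[str]:
    """All problems at once; an empty list means the manifest is valid."""
    problems: list[str] = []
    if not manifest.samples:
        problems.append("manifest lists no samples")
    seen: set[str] = set()
    for s in manifest.samples:
        if not s.sample_id:
            problems.append("sample with empty sample_id")
        elif s.sample_id in seen:
            problems.append(f"duplicate sample_id {s.sample_id!r}")
        seen.add(s.sample_id)
        if s.material not in _MATERIALS:
            problems.append(f"{s.sample_id}: unknown material {s.material!r}")
        if not s.path or not Path(s.path).exists():
            problems.append(f"{s.sample_id}: input file {s.path!r} does not exist")
    pairs: dict[str, list[ManifestSample]] = {}
    for s in manifest.samples:
        if s.pair_id:
            pairs.setdefault(s.pair_id, []).append(s)
    for pair_id, members in pairs.items():
        materials = sorted(m.material for m in members)
        if materials != ["WBC", "cfDNA"]:
            problems.append(
                f"pair {pair_id!r}: expected one cfDNA and one WBC sample, "
                f"got {materials}"
            )
    for name, p in (("panel", manifest.panel_path), ("reference", manifest.reference_path)):
        if not p or not Path(p).exists():
            problems.append(f"{name} path {p!r} does not exist")
    if manifest.hotspots_path and not Path(manifest.hotspots_path).exists():
        problems.append(f"hotspots path {manifest.hotspots_path!r} does not exist")
    return problems


@dataclass
class RunReport:
    """Self-contained JSON-serializable record of one pipeline run."""

    version: str
    config: dict
    config_hash: str
    samples: dict[str, dict] = field(default_factory=dict)
    pairs: dict[str, dict] = field(default_factory=dict)
    gene_ranking: list[dict] = field(default_factory=list)
    errors: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _load_sample_profile(
    sample: ManifestSample,
    panel: PanelDefinition,
    reference: dict[str, str],
    filter_config: FilterConfig,
) -> tuple[SampleProfile, dict]:
    path = Path(sample.path)
    if path.suffix in {".sam", ".bam", ".cram"}:
        tally = FilterTally()
        reads = read_alignments(path, panel, reference)
        columns = build_pileup(filter_reads(reads, filter_config, tally), panel, reference)
        stage_counts = tally.as_dict()
    else:  # mpileup text
        columns = read_pileup(path)
        stage_counts = {"pileup_columns_in": len(columns)}
    profile = profile_from_pileup(columns, sample.sample_id, sample.material)
    filtered = filter_positions(
        profile,
        min_depth=filter_config.min_locus_depth,
    )
    stage_counts["positions_profiled"] = len(profile)
    stage_counts["positions_kept"] = len(filtered)
    stage_counts["positions_removed"] = len(profile) - len(filtered)
    return filtered, stage_counts


def run_pipeline(
    manifest: RunManifest,
    filter_config: FilterConfig = FilterConfig(),
    min_corr_depth: int = 10000,
    min_corr_maf: float = 0.003,
    call_min_vaf: float = 0.01,
    call_min_depth: int = 5000,
    wbc_max_vaf: float = 0.01,
) -> RunReport:
    """Run the full analysis for every manifest sample and pair."""
    problems = validate_manifest(manifest)
    if problems:
        raise ValueError("invalid manifest:\n" + "\n".join(f"- {p}" for p in problems))

    effective = {
        "filter": dataclasses.asdict(filter_config),
        "min_corr_depth": min_corr_depth,
        "min_corr_maf": min_corr_maf,
        "call_min_vaf": call_min_vaf,
        "call_min_depth": call_min_depth,
        "wbc_max_vaf": wbc_max_vaf,
    }
    config_hash = hashlib.sha256(
        json.dumps(effective, sort_keys=True).encode()
    ).hexdigest()[:16]
    report = RunReport(version=__version__, config=effective, config_hash=config_hash)

    panel = load_panel(
        manifest.panel_path,
        manifest.hotspots_path or None,
    )
    reference = load_reference(manifest.reference_path)

    profiles: dict[str, SampleProfile] = {}
    for sample in manifest.samples:
        try:
            profile, counts = _load_sample_profile(sample, panel, reference, filter_config)
        except Exception as exc:  # isolate the failing sample
            logger.exception("sample %s failed", sample.sample_id)
            report.errors[sample.sample_id] = f"{type(exc).__name__}: {exc}"
            continue
        profiles[sample.sample_id] = profile
        report.samples[sample.sample_id] = {
            "material": sample.material,
            "pair_id": sample.pair_id,
            "mean_depth": profile.mean_depth,
            **counts,
        }

    by_pair: dict[str, dict[str, SampleProfile]] = {}
    for sample in manifest.samples:
        if sample.pair_id and sample.sample_id in profiles:
            by_pair.setdefault(sample.pair_id, {})[sample.material] = profiles[sample.sample_id]

    for pair_id, members in sorted(by_pair.items()):
        if set(members) != {"cfDNA", "WBC"}:
            continue
        wbc, cf = members["WBC"], members["cfDNA"]
        entry: dict = {}
        try:
            v = individual_paired_vector(wbc, cf, min_corr_depth, min_corr_maf)
            result = paired_correlation(v)
            entry["correlation"] = dataclasses.asdict(result)
        except ValueError as exc:
            entry["correlation_error"] = str(exc)
        if panel.hotspots:
            cf_calls = call_hotspots(cf, panel.hotspots, call_min_vaf, call_min_depth)
            kept = subtract_wbc_background(cf_calls, wbc, wbc_max_vaf)
            entry["cfdna_calls"] = len(cf_calls)
            entry["cfdna_calls_after_wbc_filter"] = len(kept)
            entry["calls"] = [
                {
                    "contig": c.contig,
                    "position": c.position,
                    "ref": c.ref_base,
                    "alt": c.alt_base,
                    "vaf": c.vaf,
                    "depth": c.depth,
                    "flags": list(c.flags),
                }
                for c in kept
            ]
        report.pairs[pair_id] = entry

    cf_profiles = [p for p in profiles.values() if p.material == "cfDNA"]
    if cf_profiles:
        report.gene_ranking = [
            {"gene": gene, "mean_f_gene": value, "rank": i + 1}
            for i, (gene, value) in enumerate(rank_genes(cf_profiles, panel))
        ]
    return report
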