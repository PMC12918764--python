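"""Pipeline orchestration: filter → merge → region-filter → interpret.

A run is described by one YAML config naming the per-caller input VCFs,
the platform class, the merge configuration, optional blacklist/gap
tracks, the annotation bundle and the rubric. The platform class routes
behaviour: WES uses the coarser size bins, and the blacklist/gap filters
apply to short-read platforms only (read-depth artifacts in low-mappability
regions are a short-read phenomenon).

Every stage writes its intermediate output into the run directory, and a
manifest records input digests plus per-stage record counts, so a rerun
with identical inputs is reproducible (and byte-identical apart from the
manifest timestamp).
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import cnvcurate
from cnvcurate import acmg_engine, io_vcf_bed
from cnvcurate.annotation_resources import load_resources
from cnvcurate.caller_filters import (FILTER_REGISTRY, PASS_THROUGH_CALLERS,
                                      apply_caller_filters)
from cnvcurate.ensemble_merge import MergeConfig, merge_call_sets
from cnvcurate.io_vcf_bed import read_bed_intervals, read_vcf
from cnvcurate.profiles import CallerProfile
from cnvcurate.region_filters import RegionSet, filter_by_regions

log = logging.getLogger(__name__)

PLATFORM_CLASSES = ("HD-WGS", "LD-WGS", "WES", "PB", "ONT")
SHORT_READ_PLATFORMS = ("HD-WGS", "LD-WGS", "WES")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    platform_class: str
    inputs: list  # of {"caller": str, "vcf": path, "profile": optional path}
    resources: Path
    output_dir: Path
    sample: str = "sample"
    merge: dict | str | None = None
    blacklist: Path | None = None
    gaps: Path | None = None
    rubric: Path | None = None
    missing_metric_policy: str = "lenient"
    seed: int = 0

    @property
    def short_read(self) -> bool:
        return self.platform_class in SHORT_READ_PLATFORMS

    @property
    def bin_platform(self) -> str:
        return "WES" if self.platform_class == "WES" else "WGS_LRS"


def validate_config(path) -> RunConfig:
    """Parse and cross-check a run config; all violations reported at once."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    problems = []
    platform = doc.get("platform_class", "")
    if platform not in PLATFORM_CLASSES:
        problems.append(f"platform_class must be one of {PLATFORM_CLASSES}, "
                        f"got {platform!r}")
    inputs = doc.get("inputs") or []
    if not inputs:
        problems.append("inputs: at least one caller VCF is required")
    registered = set(FILTER_REGISTRY) | PASS_THROUGH_CALLERS
    for i, item in enumerate(inputs):
        caller = str(item.get("caller", "")).lower()
        if caller not in registered:
            problems.append(f"inputs[{i}]: unknown caller {caller!r}")
        vcf = item.get("vcf")
        if not vcf or not Path(vcf).exists():
            problems.append(f"inputs[{i}]: vcf path {vcf!r} does not exist")
    for key in ("resources",):
        if not doc.get(key) or not Path(doc[key]).exists():
            problems.append(f"{key}: path {doc.get(key)!r} does not exist")
    for key in ("blacklist", "gaps", "rubric"):
        if doc.get(key) and not Path(doc[key]).exists():
            problems.append(f"{key}: path {doc[key]!r} does not exist")
    if platform in ("PB", "ONT") and (doc.get("blacklist") or doc.get("gaps")):
        log.warning("region files supplied for long-read platform %s; "
                    "blacklist/gap filtering applies to short-read data only",
                    platform)
    if problems:
        raise ConfigError("invalid run config:\n  " + "\n  ".join(problems))
    return RunConfig(
        platform_class=platform,
        inputs=[{"caller": str(i["caller"]).lower(), "vcf": Path(i["vcf"]),
                 "profile": Path(i["profile"]) if i.get("profile") else None}
                for i in inputs],
        resources=Path(doc["resources"]),
        output_dir=Path(doc.get("output_dir", "cnvcurate_run")),
        sample=str(doc.get("sample", "sample")),
        merge=doc.get("merge"),
        blacklist=Path(doc["blacklist"]) if doc.get("blacklist") else None,
        gaps=Path(doc["gaps"]) if doc.get("gaps") else None,
        rubric=Path(doc["rubric"]) if doc.get("rubric") else None,
        missing_metric_policy=doc.get("missing_metric_policy", "lenient"),
        seed=int(doc.get("seed", 0)),
    )


@dataclass
class RunManifest:
    tool_version: str
    config_digest: str
    input_digests: dict
    stage_counts: dict = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps({
            "tool_version": self.tool_version,
            "config_digest": self.config_digest,
            "input_digests": self.input_digests,
            "stage_counts": self.stage_counts,
            "timestamp": self.timestamp,
        }, indent=1, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _merge_config(config: RunConfig) -> MergeConfig:
    callers = [item["caller"] for item in config.inputs]
    if config.merge is None:
        return MergeConfig.default(callers, config.bin_platform)
    if isinstance(config.merge, (str, Path)):
        return MergeConfig.from_yaml(config.merge)
    merge = MergeConfig.default(callers, config.bin_platform)
    merge.max_dist = float(config.merge.get("max_dist", merge.max_dist))
    return merge


def run_pipeline(config: RunConfig) -> tuple[list, RunManifest]:
    """Execute all stages; returns the report rows and the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=cnvcurate.__version__,
        config_digest=hashlib.sha256(
            json.dumps(str(config), sort_keys=True).encode()).hexdigest()[:16],
        input_digests={str(i["vcf"]): _digest(i["vcf"]) for i in config.inputs},
        timestamp=datetime.datetime.now().isoformat(timespec="seconds"),
    )

    # stage 1: ingest + caller filters
    filtered_sets = []
    total_in = total_kept = 0
    for item in config.inputs:
        profile = (CallerProfile.from_yaml(item["profile"]) if item["profile"]
                   else CallerProfile.default(item["caller"]))
        record_set = read_vcf(item["vcf"], profile, sample=None)
        record_set.sample = config.sample
        survivors, report = apply_caller_filters(
            record_set, policy=config.missing_metric_policy)
        io_vcf_bed.write_calls(survivors, out / f"filtered.{item['caller']}.vcf")
        total_in += report.input_count
        total_kept += report.kept_count
        filtered_sets.append(survivors)
    manifest.stage_counts["caller_input"] = total_in
    manifest.stage_counts["caller_filtered"] = total_kept

    # stage 2: ensemble merge
    merge_config = _merge_config(config)
    consensus = merge_call_sets(filtered_sets, merge_config)
    manifest.stage_counts["consensus"] = len(consensus)
    bins_seen = sorted({m.bin_label for m in consensus})
    manifest.stage_counts["bins"] = bins_seen
    with open(out / "consensus.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\ttype\tbin\tsupport\tcallers\n")
        for m in consensus:
            fh.write(f"{m.interval.chrom}\t{m.interval.start}\t{m.interval.end}"
                     f"\t{m.type.value}\t{m.bin_label}\t{m.support_count}"
                     f"\t{','.join(sorted(m.callers))}\n")

    # stage 3: blacklist/gap region filtering (short-read platforms only)
    if config.short_read:
        for label, path in (("blacklist", config.blacklist), ("gap", config.gaps)):
            if path is None:
                continue
            regions = RegionSet(label=label, intervals=read_bed_intervals(path))
            consensus, removed = filter_by_regions(consensus, regions)
            manifest.stage_counts[f"removed_{label}"] = len(removed)
    manifest.stage_counts["region_filtered"] = len(consensus)

    # stage 4: interpretation
    resources = load_resources(config.resources)
    rubric = acmg_engine.Rubric.load(config.rubric)
    report_rows = []
    for merged in consensus:
        classification, rows = acmg_engine.interpret(
            merged.as_call(), resources, rubric)
        report_rows.extend(rows)
    manifest.stage_counts["interpreted"] = len(consensus)

    with open(out / "report.tsv", "w") as fh:
        fh.write("cnv\ttype\tcriterion\tpoints\trationale\tprovenance\n")
        for row in report_rows:
            fh.write(f"{row['cnv']}\t{row['type']}\t{row['criterion']}"
                     f"\t{row['points']:g}\t{row['rationale']}"
                     f"\t{row['provenance']}\n")
    (out / "manifest.json").write_text(manifest.to_json())
    return report_rows, manifest
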