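"""Size- and type-aware ensemble merging of multi-caller CNV calls.

Calls are partitioned by (chromosome, type, size bin) and clustered by
single linkage under a SURVIVOR-style breakpoint-proximity relation: two
calls are compatible when both start and end offsets are within
``max_dist`` — read as a fraction of the larger variant's length when
< 1 (the default 0.5), or as absolute base pairs when >= 1.

Size bins tile [50 bp, ∞):

* WGS and long-read: SS [50, 500), S [500, 5 kb), M [5 kb, 100 kb), L [100 kb, ∞)
* WES:               S [50, 10 kb), M [10 kb, 100 kb), L [100 kb, ∞)

Bins are half-open so a boundary length (e.g. exactly 500 bp) maps to
exactly one bin, the upper one. Each cluster yields one consensus CNV whose
representative interval takes the per-endpoint median of the supporting
calls (rounded down), and consensus selection keeps a cluster when enough
of its supporting callers belong to the tool set configured for that
(type, bin) cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

from cnvcurate.intervals import CnvCall, CnvType, GenomicInterval

WGS_LRS_BINS = (("SS", 50, 500), ("S", 500, 5_000),
                ("M", 5_000, 100_000), ("L", 100_000, math.inf))
WES_BINS = (("S", 50, 10_000), ("M", 10_000, 100_000), ("L", 100_000, math.inf))

_PLATFORM_BINS = {"WGS_LRS": WGS_LRS_BINS, "WES": WES_BINS}


def platform_bins(platform_class: str):
    """Bin table for a platform class; WES is depth-binned more coarsely."""
    key = "WES" if platform_class.upper() == "WES" else "WGS_LRS"
    return _PLATFORM_BINS[key]


def assign_size_bin(length: int, platform_class: str = "WGS_LRS") -> str:
    """Unique bin label whose [lower, upper) range contains the length."""
    if length < 50:
        raise ValueError(f"length {length} bp is below the 50 bp CNV minimum")
    for label, lo, hi in platform_bins(platform_class):
        if lo <= length < hi:
            return label
    raise AssertionError("bins tile [50, inf); unreachable")


def breakpoint_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    return abs(a.start - b.start) + abs(a.end - b.end)


def max_breakpoint_offset(a: GenomicInterval, b: GenomicInterval,
                          max_dist: float) -> float:
    """Allowed per-endpoint offset: fractional (<1) of the larger length, else bp."""
    if max_dist < 1:
        return max_dist * max(a.length, b.length)
    return max_dist


def breakpoints_compatible(a: CnvCall, b: CnvCall, max_dist: float = 0.5) -> bool:
    """True iff same chrom/type and both endpoint offsets are within bound."""
    if a.interval.chrom != b.interval.chrom or a.type is not b.type:
        return False
    allowed = max_breakpoint_offset(a.interval, b.interval, max_dist)
    return (abs(a.interval.start - b.interval.start) <= allowed
            and abs(a.interval.end - b.interval.end) <= allowed)


@dataclass
class MergeConfig:
    """Merge parameters: proximity bound, per-(type, bin) tool sets and support.

    ``tool_sets`` maps (CnvType, bin label) to the set of caller ids whose
    agreement counts toward consensus; ``min_support`` maps the same key to
    the minimum number of those callers that must support a cluster. The
    default config admits every registered caller and requires two
    concordant callers in the small bins (SS/S), where individual callers
    are noisiest, and one in M/L.
    """

    max_dist: float = 0.5
    platform_class: str = "WGS_LRS"
    tool_sets: dict = field(default_factory=dict)
    min_support: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_dist <= 0:
            raise ValueError("max_dist must be positive")

    @classmethod
    def default(cls, callers, platform_class: str = "WGS_LRS") -> "MergeConfig":
        callers = frozenset(c.lower() for c in callers)
        tool_sets, min_support = {}, {}
        for cnv_type in CnvType:
            for label, _, _ in platform_bins(platform_class):
                tool_sets[(cnv_type, label)] = callers
                min_support[(cnv_type, label)] = 2 if label in ("SS", "S") else 1
        return cls(tool_sets=tool_sets, min_support=min_support,
                   platform_class=platform_class)

    @classmethod
    def from_yaml(cls, path) -> "MergeConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        platform = doc.get("platform_class", "WGS_LRS")
        config = cls.default(doc.get("callers", []), platform)
        config.max_dist = float(doc.get("max_dist", 0.5))
        for key, spec in (doc.get("bins") or {}).items():
            type_token, _, label = key.partition("/")
            cell = (CnvType.parse(type_token), label)
            if "tools" in spec:
                config.tool_sets[cell] = frozenset(t.lower() for t in spec["tools"])
            if "min_support" in spec:
                config.min_support[cell] = int(spec["min_support"])
        return config


@dataclass
class MergedCnv:
    """A consensus CNV: representative interval plus its supporting calls."""

    interval: GenomicInterval
    type: CnvType
    supports: dict  # caller id -> CnvCall
    bin_label: str

    @property
    def support_count(self) -> int:
        return len(self.supports)

    @property
    def callers(self) -> frozenset:
        return frozenset(self.supports)

    def as_call(self) -> CnvCall:
        return CnvCall(interval=self.interval, type=self.type, caller="consensus")


def _median_floor(values) -> int:
    values = sorted(values)
    n = len(values)
    mid = n // 2
    if n % 2:
        return values[mid]
    return (values[mid - 1] + values[mid]) // 2


def _representative(calls) -> GenomicInterval:
    start = _median_floor([c.interval.start for c in calls])
    end = _median_floor([c.interval.end for c in calls])
    return GenomicInterval(calls[0].interval.chrom, start, end)


def _cluster_partition(calls, max_dist: float):
    """Greedy single-linkage clustering with at most one call per caller.

    Seeds are taken in sorted order; the cluster grows by adding, per
    caller not yet represented, the pool call compatible with any current
    member that lies closest to the seed. Calls a represented caller would
    contribute twice stay in the pool and seed their own clusters. With at
    most one call per caller in a connected component this reduces exactly
    to the component of the transitive closure of the compatibility
    relation.
    """
    pool = sorted(calls, key=CnvCall.sort_key)
    clusters = []
    while pool:
        seed = pool.pop(0)
        members = [seed]
        grown = True
        while grown:
            grown = False
            candidates = {}
            for call in pool:
                if call.caller in {m.caller for m in members}:
                    continue
                if any(breakpoints_compatible(call, m, max_dist) for m in members):
                    dist = breakpoint_distance(call.interval, seed.interval)
                    best = candidates.get(call.caller)
                    if best is None or (dist, call.sort_key()) < best[0]:
                        candidates[call.caller] = ((dist, call.sort_key()), call)
            for _, call in sorted(candidates.values(), key=lambda kv: kv[0]):
                if call.caller not in {m.caller for m in members}:
                    members.append(call)
                    pool.remove(call)
                    grown = True
        clusters.append(members)
    return clusters


def cluster_calls(calls, config: MergeConfig) -> list[MergedCnv]:
    """Partition by (chrom, type, bin) and cluster each partition."""
    partitions: dict = {}
    for call in calls:
        key = (call.interval.chrom, call.type,
               assign_size_bin(call.length, config.platform_class))
        partitions.setdefault(key, []).append(call)
    merged = []
    for (chrom, cnv_type, bin_label) in sorted(
            partitions, key=lambda k: (k[0], k[1].value, k[2])):
        for members in _cluster_partition(partitions[(chrom, cnv_type, bin_label)],
                                          config.max_dist):
            merged.append(MergedCnv(
                interval=_representative(members),
                type=cnv_type,
                supports={m.caller: m for m in sorted(members, key=CnvCall.sort_key)},
                bin_label=bin_label,
            ))
    merged.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end,
                               m.type.value))
    return merged


def select_consensus(merged_list, config: MergeConfig) -> list[MergedCnv]:
    """Keep clusters with enough support from the configured tool set."""
    kept = []
    for merged in merged_list:
        cell = (merged.type, merged.bin_label)
        if cell not in config.tool_sets:
            configured = ", ".join(f"{t.value}/{b}" for t, b in sorted(
                config.tool_sets, key=lambda c: (c[0].value, c[1])))
            raise KeyError(
                f"no tool set configured for {merged.type.value}/{merged.bin_label}; "
                f"configured cells: {configured}")
        support = merged.callers & config.tool_sets[cell]
        if len(support) >= config.min_support.get(cell, 1):
            kept.append(merged)
    return kept


def merge_call_sets(record_sets, config: MergeConfig) -> list[MergedCnv]:
    """Cluster all calls from several callers and apply consensus selection."""
    calls = [call for rs in record_sets for call in rs]
    return select_consensus(cluster_calls(calls, config), config)
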