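"""Blacklist- and gap-based region filtering by reciprocal overlap.

Short-read CNV calls inside ENCODE-style mappability blacklists or
assembly gaps are unreliable; consensus CNVs with at least 70% reciprocal
overlap with any single such region are removed. Reciprocal overlap of
intervals *a* and *b* is min(o/len(a), o/len(b)) with *o* the overlap
length — symmetric, 1 exactly on identical intervals.

Overlap is assessed against individual regions, not their union: a CNV
tiled by many small blacklist intervals none of which reaches the cut-off
is kept. ``mode="union"`` switches to union semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from cnvcurate.intervals import GenomicInterval


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(o/len_a, o/len_b); 0 when on different chromosomes."""
    o = a.overlap_length(b)
    if o == 0:
        return 0.0
    return min(o / a.length, o / b.length)


@dataclass
class RegionSet:
    """An indexed set of filter regions (blacklist or gap track)."""

    label: str
    intervals: list
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, probe: GenomicInterval) -> list:
        """All regions intersecting the probe interval."""
        tree = self._trees.get(probe.chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.overlap(probe.start, probe.end))

    def union_overlap_length(self, probe: GenomicInterval) -> int:
        """Bases of the probe covered by the union of overlapping regions."""
        segments = sorted((max(iv.start, probe.start), min(iv.end, probe.end))
                          for iv in self.overlapping(probe))
        covered = 0
        cursor = probe.start
        for lo, hi in segments:
            lo = max(lo, cursor)
            if hi > lo:
                covered += hi - lo
                cursor = hi
        return covered


def max_reciprocal_overlap(probe: GenomicInterval, regions: RegionSet) -> float:
    return max((reciprocal_overlap(probe, iv) for iv in regions.overlapping(probe)),
               default=0.0)


def filter_by_regions(cnvs, regions: RegionSet, threshold: float = 0.70,
                      mode: str = "single") -> tuple[list, list]:
    """Split CNVs into (kept, removed) by reciprocal overlap with regions.

    A CNV is removed when its reciprocal overlap with any single region is
    >= threshold (``mode="single"``), or when the union of overlapping
    regions covers >= threshold of both the CNV and, degenerately, itself
    (``mode="union"``: the union coverage fraction of the CNV is compared
    to the threshold).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(regions) == 0:
        import logging
        logging.getLogger(__name__).warning(
            "empty %s region set: nothing filtered", regions.label)
        return list(cnvs), []
    kept, removed = [], []
    for cnv in cnvs:
        probe = cnv.interval if hasattr(cnv, "interval") else cnv
        if mode == "single":
            hit = max_reciprocal_overlap(probe, regions) >= threshold
        elif mode == "union":
            hit = regions.union_overlap_length(probe) / probe.length >= threshold
        else:
            raise ValueError(f"unknown mode {mode!r}; use 'single' or 'union'")
        (removed if hit else kept).append(cnv)
    return kept, removed
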