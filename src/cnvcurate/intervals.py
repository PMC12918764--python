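"""Core domain types: genomic intervals and CNV calls.

All coordinates inside the package are 0-based half-open ([start, end)),
the BED convention. VCF input/output converts at the boundary and nowhere
else. Chromosome names are stored without a ``chr`` prefix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

MIN_CNV_LENGTH = 50  # bp; events below this are not CNVs for our purposes


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix; 'chrX' and 'X' denote the same sequence."""
    if not chrom:
        raise ValueError("empty chromosome name")
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


class CnvType(enum.Enum):
    """Copy-number variant type: loss (DEL) or gain (DUP)."""

    DEL = "DEL"
    DUP = "DUP"

    @classmethod
    def parse(cls, token: str) -> "CnvType":
        token = token.strip().upper()
        aliases = {"DEL": cls.DEL, "DUP": cls.DUP, "LOSS": cls.DEL, "GAIN": cls.DUP,
                   "<DEL>": cls.DEL, "<DUP>": cls.DUP, "DUP:TANDEM": cls.DUP}
        if token not in aliases:
            raise ValueError(f"unknown CNV type token {token!r}")
        return aliases[token]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    Invariants: ``0 <= start < end`` and a non-empty, normalized chromosome
    name (no ``chr`` prefix).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies entirely within self (same chromosome)."""
        return (self.chrom == other.chrom
                and self.start <= other.start and other.end <= self.end)

    def __str__(self) -> str:  # 1-based inclusive, the human convention
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class CnvCall:
    """One CNV record as reported by a single caller.

    ``metrics`` holds the caller-specific quality numbers the confidence
    filters consume (e.g. ``pytorP1`` for CNVpytor, ``BF`` for ExomeDepth,
    ``QS``/``CN``/``nt`` for the GATK4 germline CNV caller). ``filter_status``
    is the set of VCF FILTER labels plus, when present, the per-sample FT
    genotype-filter label stored under key ``FT:<label>`` is *not* used;
    instead the FT label is carried in ``genotype_filter``.
    """

    interval: GenomicInterval
    type: CnvType
    caller: str
    genotype: Optional[str] = None
    genotype_filter: Optional[str] = None
    filter_status: frozenset = frozenset()
    quality: Optional[float] = None
    metrics: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.interval.length

    def sort_key(self) -> tuple:
        return (self.interval.chrom, self.interval.start, self.interval.end,
                self.type.value, self.caller)


@dataclass
class CnvRecordSet:
    """All calls of one caller for one sample, sorted by (chrom, start)."""

    sample: str
    caller: str
    assembly: str = "GRCh38"
    calls: list = field(default_factory=list)
    skipped: int = 0  # non-DEL/DUP or unparseable records dropped at load time

    def __post_init__(self) -> None:
        for c in self.calls:
            if c.caller != self.caller:
                raise ValueError(
                    f"call caller {c.caller!r} != record set caller {self.caller!r}")
        self.sort()

    def sort(self) -> None:
        self.calls.sort(key=CnvCall.sort_key)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)
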