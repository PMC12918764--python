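"""Caller-specific confidence filters.

Each CNV caller ships its own quality metrics, and each gets its own
exclusion rule, applied as a pure predicate over a single call:

* CNVpytor    — exclude if pytorP1 > 0.05, Q0 > 0.9, or read-depth ratio in
                the near-diploid band 0.75 < pytorRD < 1.25.
* ControlFREEC— exclude if Wilcoxon p (W) > 0.05 or Kolmogorov–Smirnov p
                (KS) > 0.05.
* delly/Manta — require PASS in both the site FILTER and the per-sample FT
                genotype filter; drop hom-ref (0/0) genotypes.
* lumpy       — exclude if QUAL < 120.
* Wham        — exclude if max_CW < 0.2, DELs with TF < 3, DUPs with U < 2.
* GRIDSS      — exclude calls flagged NO_ASSEMBLY.
* ExomeDepth  — exclude if BF < 15, DELs with observed/expected read ratio
                > 0.8, DUPs with ratio < 1.1.
* GATK4 gCNV  — exclude if the quality score QS falls below a piecewise
                threshold in the number of exons spanned (nt):
                DEL CN=0: min(1000, max(400, 10*nt));
                DEL CN=1: min(1000, max(100, 10*nt));
                DUP:      min(400,  max(50,  4*nt)).

All inequalities are strict, exactly as each rule is stated; a value equal
to its threshold is on the keep side. Callers with no stated rule (cn.mops,
xhmm, ECOLE, the long-read callers) pass through unfiltered.

Missing metrics are handled by a policy switch: ``strict`` raises,
``lenient`` (default) keeps the call and logs a warning — caller output
dialects vary across versions and a missing key should not silently drop
data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from cnvcurate.intervals import CnvCall, CnvRecordSet, CnvType

log = logging.getLogger(__name__)


class MissingMetricError(KeyError):
    pass


@dataclass
class FilterOutcome:
    """Result of one rule bundle on one call: kept iff no reason fired."""

    kept: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.kept == (not self.reasons)


@dataclass
class FilterReport:
    """Per-rule removal counts for one call set."""

    caller: str
    input_count: int = 0
    kept_count: int = 0
    removed_by_reason: dict = field(default_factory=dict)

    def record(self, outcome: FilterOutcome) -> None:
        self.input_count += 1
        if outcome.kept:
            self.kept_count += 1
        for reason in outcome.reasons:
            self.removed_by_reason[reason] = self.removed_by_reason.get(reason, 0) + 1


def _metric(call: CnvCall, name: str, policy: str):
    if name in call.metrics:
        return call.metrics[name]
    if policy == "strict":
        raise MissingMetricError(
            f"{call.caller} call {call.interval} lacks metric {name!r}")
    log.warning("%s call %s lacks metric %r; kept (lenient policy)",
                call.caller, call.interval, name)
    return None


def _outcome(reasons) -> FilterOutcome:
    reasons = [r for r in reasons if r]
    return FilterOutcome(kept=not reasons, reasons=reasons)


def filter_cnvpytor(call: CnvCall, policy: str = "lenient",
                    conjunctive: bool = False) -> FilterOutcome:
    """CNVpytor rule; by default the three conditions exclude disjunctively.

    The two pytorRD bounds form a single band condition (read depth near
    diploid, likely an artifact). ``conjunctive=True`` requires all
    conditions to fire before excluding.
    """
    p1 = _metric(call, "pytorP1", policy)
    q0 = _metric(call, "Q0", policy)
    rd = _metric(call, "pytorRD", policy)
    fired = []
    if p1 is not None and p1 > 0.05:
        fired.append("pytorP1")
    if q0 is not None and q0 > 0.9:
        fired.append("Q0")
    if rd is not None and 0.75 < rd < 1.25:
        fired.append("pytorRD")
    if conjunctive:
        return _outcome(fired if len(fired) == 3 else [])
    return _outcome(fired)


def filter_controlfreec(call: CnvCall, policy: str = "lenient") -> FilterOutcome:
    w = _metric(call, "W", policy)
    ks = _metric(call, "KS", policy)
    return _outcome([
        "W" if w is not None and w > 0.05 else None,
        "KS" if ks is not None and ks > 0.05 else None,
    ])


def filter_pass_gt(call: CnvCall, policy: str = "lenient") -> FilterOutcome:
    """delly/Manta rule: PASS in site and genotype filters; no 0/0 genotype."""
    reasons = []
    site_pass = call.filter_status == frozenset({"PASS"}) or not call.filter_status
    if not site_pass:
        reasons.append("site_filter")
    if call.genotype_filter is not None and call.genotype_filter != "PASS":
        reasons.append("genotype_filter")
    gt = (call.genotype or "").replace("|", "/")
    if gt == "0/0":
        reasons.append("hom_ref_genotype")
    elif not call.genotype:
        log.debug("%s call %s has no genotype; treated as non-0/0",
                  call.caller, call.interval)
    return _outcome(reasons)


def filter_lumpy(call: CnvCall, policy: str = "lenient") -> FilterOutcome:
    if call.quality is None:
        if policy == "strict":
            raise MissingMetricError(f"lumpy call {call.interval} lacks QUAL")
        log.warning("lumpy call %s lacks QUAL; kept (lenient policy)", call.interval)
        return _outcome([])
    return _outcome(["quality" if call.quality < 120 else None])


def filter_wham(call: CnvCall, policy: str = "lenient") -> FilterOutcome:
    max_cw = _metric(call, "max_CW", policy)
    reasons = []
    if max_cw is not None and max_cw < 0.2:
        reasons.append("max_CW")
    if call.type is CnvType.DEL:
        tf = _metric(call, "TF", policy)
        if tf is not None and tf < 3:
            reasons.append("TF")
    else:
        u = _metric(call, "U", policy)
        if u is not None and u < 2:
            reasons.append("U")
    return _outcome(reasons)


def filter_gridss(call: CnvCall, policy: str = "lenient") -> FilterOutcome:
    return _outcome(["NO_ASSEMBLY" if "NO_ASSEMBLY" in call.filter_status else None])


def filter_exomedepth(call: CnvCall, policy: str = "lenient") -> FilterOutcome:
    bf = _metric(call, "BF", policy)
    ratio = _metric(call, "reads_ratio", policy)
    reasons = []
    if bf is not None and bf < 15:
        reasons.append("BF")
    if ratio is not None:
        if call.type is CnvType.DEL and ratio > 0.8:
            reasons.append("reads_ratio")
        elif call.type is CnvType.DUP and ratio < 1.1:
            reasons.append("reads_ratio")
    return _outcome(reasons)


def gatk4_qs_threshold(cnv_type: CnvType, cn: int, nt: int) -> float:
    """Piecewise QS threshold in the exon-span count nt (>= 1)."""
    if nt < 1:
        raise ValueError(f"exon-span count nt must be >= 1, got {nt}")
    if cnv_type is CnvType.DUP:
        return min(400, max(50, 4 * nt))
    if cn == 0:
        return min(1000, max(400, 10 * nt))
    if cn == 1:
        return min(1000, max(100, 10 * nt))
    raise ValueError(f"no DEL threshold for copy-number state {cn}")


def filter_gatk4(call: CnvCall, policy: str = "lenient") -> FilterOutcome:
    qs = _metric(call, "QS", policy)
    nt = _metric(call, "nt", policy)
    if qs is None or nt is None:
        return _outcome([])
    if call.type is CnvType.DEL:
        cn = _metric(call, "CN", policy)
        if cn is None:
            return _outcome([])
        cn = int(cn)
        if cn not in (0, 1):
            log.warning("GATK4 DEL %s has CN=%d; QS rule not applicable, kept",
                        call.interval, cn)
            return _outcome([])
        threshold = gatk4_qs_threshold(CnvType.DEL, cn, int(nt))
    else:
        threshold = gatk4_qs_threshold(CnvType.DUP, -1, int(nt))
    return _outcome(["QS" if qs < threshold else None])


# caller id -> rule bundle; callers absent here pass through unfiltered
FILTER_REGISTRY = {
    "cnvpytor": filter_cnvpytor,
    "controlfreec": filter_controlfreec,
    "delly": filter_pass_gt,
    "manta": filter_pass_gt,
    "lumpy": filter_lumpy,
    "wham": filter_wham,
    "gridss": filter_gridss,
    "exomedepth": filter_exomedepth,
    "gatk4": filter_gatk4,
}

PASS_THROUGH_CALLERS = frozenset({
    "cn.mops", "xhmm", "ecole",
    "cutesv", "svision-pro", "sniffles", "nanovar", "debreak",
})


def evaluate_call(call: CnvCall, policy: str = "lenient") -> FilterOutcome:
    """Apply the call's caller rule bundle; pass-through callers always keep."""
    caller = call.caller.lower()
    rule = FILTER_REGISTRY.get(caller)
    if rule is None:
        if caller in PASS_THROUGH_CALLERS:
            return FilterOutcome(kept=True)
        raise KeyError(
            f"unknown caller {call.caller!r}; registered: "
            f"{', '.join(sorted(set(FILTER_REGISTRY) | PASS_THROUGH_CALLERS))}")
    return rule(call, policy=policy)


def apply_caller_filters(record_set: CnvRecordSet,
                         policy: str = "lenient") -> tuple[CnvRecordSet, FilterReport]:
    """Filter a call set, returning survivors and per-rule removal counts."""
    report = FilterReport(caller=record_set.caller)
    survivors = []
    for call in record_set:
        outcome = evaluate_call(call, policy=policy)
        report.record(outcome)
        if outcome.kept:
            survivors.append(call)
    filtered = CnvRecordSet(sample=record_set.sample, caller=record_set.caller,
                            assembly=record_set.assembly, calls=survivors,
                            skipped=record_set.skipped)
    return filtered, report
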