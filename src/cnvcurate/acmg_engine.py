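"""Semiquantitative ACMG/ClinGen scoring of CNVs.

Each CNV is scored against five evidence sections — genomic content,
dosage-sensitivity overlap, gene number, population frequency / reported
cases, and inheritance — and the summed points map onto a five-tier
classification:

    total >=  0.99            Pathogenic
    0.90 <= total <= 0.98     Likely pathogenic
   -0.89 <= total <= 0.89     Uncertain significance (VUS)
   -0.98 <= total <= -0.90    Likely benign
    total <= -0.99            Benign

Sections 1–4 are scored automatically from the annotation bundle; clinical
case, segregation and de-novo criteria (the rest of Section 4 and all of
Section 5) enter through :func:`merge_user_evidence`, mirroring the manual
review step of clinical practice. The point values, ranges and bands live
in an editable rubric data file.

Intragenic deletions are graded through a loss-of-function (PVS1-style)
decision tree: does the deletion remove coding sequence; does it shift the
reading frame; is the resulting premature stop predicted to trigger
nonsense-mediated decay (terminating upstream of the last exon–exon
junction minus 50 nt); and, for NMD-escaping or in-frame events, how much
protein is removed (>10% steps strength up) and do curated pathogenic
variants lie in or downstream of the removed region.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field

import yaml

from cnvcurate.annotation_resources import (DosageRegion, GeneRecord,
                                            ResourceBundle, predicted_hi)
from cnvcurate.intervals import CnvCall, CnvType, GenomicInterval


class Category(enum.Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "Likely pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "Likely benign"
    BENIGN = "Benign"


class Pvs1Strength(enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    NONE = "none"


@dataclass
class Pvs1Result:
    strength: Pvs1Strength
    path: list  # decision-tree trace, outermost node first


@dataclass
class EvidenceItem:
    criterion: str
    points: float
    rationale: str
    auto: bool = True


@dataclass
class Classification:
    total: float
    category: Category
    evidence: list


class Rubric:
    """Criterion metadata, gene-count bands and classification bands."""

    def __init__(self, doc: dict):
        self.doc = doc
        self.criteria = doc["criteria"]
        self.bands = doc["classification_bands"]
        self.gene_count_bands = doc["gene_count_bands"]
        self.pvs1_points = doc["pvs1_points"]
        self.common_af_threshold = float(doc.get("common_af_threshold", 0.01))
        for cid, meta in self.criteria.items():
            if not meta["min"] <= meta["default"] <= meta["max"]:
                raise ValueError(f"rubric criterion {cid}: default outside [min,max]")

    @classmethod
    def load(cls, path=None) -> "Rubric":
        if path is None:
            ref = importlib.resources.files("cnvcurate.data") / "rubric.yaml"
            doc = yaml.safe_load(ref.read_text())
        else:
            with open(path) as fh:
                doc = yaml.safe_load(fh)
        return cls(doc)

    def validate_item(self, item: EvidenceItem) -> None:
        meta = self.criteria.get(item.criterion)
        if meta is None:
            raise KeyError(f"unknown rubric criterion {item.criterion!r}")
        if not meta["min"] <= item.points <= meta["max"]:
            raise ValueError(
                f"criterion {item.criterion}: points {item.points} outside "
                f"[{meta['min']}, {meta['max']}]")

    def item(self, criterion: str, rationale: str, points: float | None = None,
             auto: bool = True) -> EvidenceItem:
        meta = self.criteria[criterion]
        item = EvidenceItem(criterion=criterion,
                            points=meta["default"] if points is None else points,
                            rationale=rationale, auto=auto)
        self.validate_item(item)
        return item


def _prefix(cnv_type: CnvType) -> str:
    return "L" if cnv_type is CnvType.DEL else "G"


# ---------------------------------------------------------------------------
# Section 1: genomic content

def evaluate_section1(cnv: CnvCall, resources: ResourceBundle,
                      rubric: Rubric) -> EvidenceItem:
    """1A if the CNV touches protein-coding genes or dosage elements, else 1B."""
    p = _prefix(cnv.type)
    genes = resources.overlapping_genes(cnv.interval)
    if genes:
        return rubric.item(f"{p}1A",
                           f"overlaps {len(genes)} protein-coding gene(s)")
    elements = resources.dosage_hits(cnv.interval, cnv.type)
    if elements:
        return rubric.item(f"{p}1A",
                           "overlaps a curated dosage-sensitive element")
    return rubric.item(f"{p}1B", "no protein-coding genes or known "
                                 "functionally important elements")


# ---------------------------------------------------------------------------
# PVS1-style loss-of-function assessment for intragenic events

def assess_pvs1_loss(cnv: CnvCall, gene: GeneRecord,
                     curated_variants=()) -> Pvs1Result:
    """Grade an intragenic/partial deletion through the LoF decision tree.

    ``curated_variants`` are the bundle's entries for this gene; the
    very-strong branch additionally requires a loss-of-function disease
    mechanism (disease-associated gene with curated null variants), and
    last-exon pathogenic variants let NMD-escaping events keep strong
    strength.
    """
    model = gene.exon_model
    trace = [f"gene={gene.symbol}"]
    if model.coding_length == 0:
        trace.append("no CDS annotation")
        return Pvs1Result(Pvs1Strength.NONE, trace)
    removed, min_offset = model.deleted_coding_offsets(cnv.interval)
    if removed == 0:
        trace.append("no coding exon removed")
        return Pvs1Result(Pvs1Strength.NONE, trace)
    trace.append(f"removes {removed} coding bases")
    frameshift = removed % 3 != 0
    fraction_removed = removed / model.coding_length
    lof_mechanism = gene.disease_associated and any(
        v.is_null and v.is_pathogenic for v in curated_variants)

    pathogenic_in_or_after = []
    for var in curated_variants:
        if not var.is_pathogenic:
            continue
        off = model.coding_offset(var.position)
        if var.in_last_exon or (off is not None and min_offset is not None
                                and off >= min_offset):
            pathogenic_in_or_after.append(var)

    if frameshift:
        trace.append("frameshift")
        nmd_competent = (min_offset is not None
                         and min_offset < model.nmd_boundary_offset())
        if nmd_competent:
            trace.append("NMD predicted (stop upstream of last junction - 50 nt)")
            if lof_mechanism:
                trace.append("LoF is an established disease mechanism")
                return Pvs1Result(Pvs1Strength.VERY_STRONG, trace)
            trace.append("LoF disease mechanism not established")
            return Pvs1Result(Pvs1Strength.MODERATE, trace)
        trace.append("NMD escape")
        if pathogenic_in_or_after:
            trace.append("curated pathogenic variant in/after the removed region")
            return Pvs1Result(Pvs1Strength.STRONG, trace)
    else:
        trace.append("in-frame")
        if pathogenic_in_or_after:
            trace.append("curated pathogenic variant in the removed region")
            return Pvs1Result(Pvs1Strength.STRONG, trace)
    if fraction_removed > 0.10:
        trace.append(f"removes {fraction_removed:.1%} of the protein (>10%)")
        return Pvs1Result(Pvs1Strength.STRONG, trace)
    trace.append(f"removes {fraction_removed:.1%} of the protein (<=10%)")
    return Pvs1Result(Pvs1Strength.MODERATE, trace)


# ---------------------------------------------------------------------------
# Section 2

def _contained_elements(cnv, hits):
    """Hits whose whole element lies within the CNV (coverage fraction 1)."""
    return [(el, f) for el, f in hits if f >= 1.0]


def evaluate_section2_loss(cnv: CnvCall, resources: ResourceBundle,
                           rubric: Rubric) -> list:
    """Dosage-sensitivity evidence for deletions, in rubric priority order.

    2A complete HI overlap (+1.0) > intragenic/partial HI-gene overlap via
    the PVS1 tree (2C/2D/2E) > benign-region containment 2F (−1.0) /
    benign-plus-genes 2G (0) > predicted-HI 2H (+0.15). When several could
    fire, the highest-priority one is scored and the alternatives are noted
    in its rationale.
    """
    assert cnv.type is CnvType.DEL
    hits = resources.dosage_hits(cnv.interval, cnv.type)
    hi_hits = [(el, f) for el, f in hits
               if isinstance(el, GeneRecord)
               or el.kind == "HI_region"]
    benign_hits = [(el, f) for el, f in hits
                   if isinstance(el, DosageRegion) and el.kind == "benign_loss_region"]

    complete_hi = _contained_elements(cnv, hi_hits)
    if complete_hi:
        labels = ", ".join(el.symbol if isinstance(el, GeneRecord) else el.label
                           for el, _ in complete_hi)
        return [rubric.item("L2A", f"complete overlap of established HI "
                                   f"element(s): {labels}")]

    partial_hi_genes = [(el, f) for el, f in hi_hits if isinstance(el, GeneRecord)]
    if partial_hi_genes:
        best_item = None
        for gene, _ in partial_hi_genes:
            kind = dict(resources.overlapping_genes(cnv.interval)).get(gene)
            result = assess_pvs1_loss(
                cnv, gene, resources.variants_in_gene(gene.symbol))
            points = rubric.pvs1_points[result.strength.value]
            criterion = {"internal": "L2E", "partial_5prime": "L2C",
                         "partial_3prime": "L2D"}.get(kind, "L2E")
            rationale = (f"{criterion[-1]}-type overlap of HI gene {gene.symbol}; "
                         f"PVS1 {result.strength.value}: " + " -> ".join(result.path))
            item = rubric.item(criterion, rationale, points=points)
            if best_item is None or abs(item.points) > abs(best_item.points):
                best_item = item
        return [best_item]

    partial_hi_regions = [(el, f) for el, f in hi_hits
                          if isinstance(el, DosageRegion)]
    if partial_hi_regions:
        label = partial_hi_regions[0][0].label
        return [rubric.item("L2B", f"partial overlap of HI region {label}")]

    for region, _ in benign_hits:
        if region.interval.contains(cnv.interval):
            outside = [g for g, _ in resources.overlapping_genes(cnv.interval)
                       if not region.interval.contains(g.interval)]
            if not outside:
                return [rubric.item(
                    "L2F", f"contained within benign loss region {region.label}")]
            return [rubric.item(
                "L2G", f"within benign loss region {region.label} but includes "
                       f"additional gene(s): {', '.join(g.symbol for g in outside)}")]
    if benign_hits:
        return [rubric.item(
            "L2G", f"overlaps benign loss region {benign_hits[0][0].label} and "
                   "additional sequence")]

    hi_predicted = [g for g, _ in resources.overlapping_genes(cnv.interval)
                    if predicted_hi(g)]
    if hi_predicted:
        return [rubric.item(
            "L2H", "predicted haploinsufficient gene(s): "
                   + ", ".join(g.symbol for g in hi_predicted))]
    return []


def evaluate_section2_gain(cnv: CnvCall, resources: ResourceBundle,
                           rubric: Rubric) -> list:
    """Dosage evidence for duplications, mirroring the loss arm over TS elements.

    Partial or intragenic duplications take conservative defaults (0
    points) because tandem-vs-inserted orientation is unknown from a
    depth-based call.
    """
    assert cnv.type is CnvType.DUP
    hits = resources.dosage_hits(cnv.interval, cnv.type)
    ts_hits = [(el, f) for el, f in hits
               if isinstance(el, GeneRecord) or el.kind == "TS_region"]
    benign_hits = [(el, f) for el, f in hits
                   if isinstance(el, DosageRegion) and el.kind == "benign_gain_region"]

    complete_ts = _contained_elements(cnv, ts_hits)
    if complete_ts:
        labels = ", ".join(el.symbol if isinstance(el, GeneRecord) else el.label
                           for el, _ in complete_ts)
        return [rubric.item("G2A", f"complete overlap of established TS "
                                   f"element(s): {labels}")]
    for region, _ in benign_hits:
        if region.interval.contains(cnv.interval):
            outside = [g for g, _ in resources.overlapping_genes(cnv.interval)
                       if not region.interval.contains(g.interval)]
            if not outside:
                return [rubric.item(
                    "G2C", f"contained within benign gain region {region.label}")]
            return [rubric.item(
                "G2D", f"within benign gain region {region.label} but includes "
                       f"additional gene(s): {', '.join(g.symbol for g in outside)}")]
    if ts_hits:
        label = ts_hits[0][0].label if isinstance(ts_hits[0][0], DosageRegion) \
            else ts_hits[0][0].symbol
        return [rubric.item("G2B", f"partial overlap of TS element {label}")]

    broken = [g for g, kind in resources.overlapping_genes(cnv.interval)
              if kind in ("internal", "partial_5prime", "partial_3prime")
              and g.disease_associated]
    if broken:
        return [rubric.item(
            "G2I", "breakpoint(s) within disease gene(s) "
                   + ", ".join(g.symbol for g in broken)
                   + "; insertion site and orientation unknown", points=0.0)]
    return []


# ---------------------------------------------------------------------------
# Sections 3 and 4

def evaluate_section3(cnv: CnvCall, resources: ResourceBundle,
                      rubric: Rubric) -> EvidenceItem:
    """Gene-number evidence from the family-collapsed gene count."""
    count = resources.count_genes(cnv.interval)
    arm = "loss" if cnv.type is CnvType.DEL else "gain"
    bands = rubric.gene_count_bands[arm]
    p = _prefix(cnv.type)
    if count >= bands["tier2_min"]:
        return rubric.item(f"{p}3C", f"{count} protein-coding genes (collapsed)")
    if count >= bands["tier1_min"]:
        return rubric.item(f"{p}3B", f"{count} protein-coding genes (collapsed)")
    return rubric.item(f"{p}3A", f"{count} protein-coding genes (collapsed)")


def evaluate_section4_frequency(cnv: CnvCall, resources: ResourceBundle,
                                rubric: Rubric,
                                ro_threshold: float = 0.70) -> EvidenceItem | None:
    """Benign evidence from common population CNVs (AF >= 1% by default)."""
    af, source = resources.max_population_frequency(cnv.interval, cnv.type,
                                                    ro_threshold)
    if af is None or af < rubric.common_af_threshold:
        return None
    return rubric.item(f"{_prefix(cnv.type)}4O",
                       f"population CNV in {source} at AF {af:g} "
                       f">= {rubric.common_af_threshold:g}")


# ---------------------------------------------------------------------------
# combination and classification

def merge_user_evidence(auto_items, user_items, rubric: Rubric) -> list:
    """Union of engine and user evidence; user items override per criterion."""
    merged = {item.criterion: item for item in auto_items}
    for item in user_items:
        rubric.validate_item(item)
        if item.criterion in merged:
            previous = merged[item.criterion]
            item.rationale += (f" [overrides automatic assignment "
                               f"{previous.points:+g}: {previous.rationale}]")
        item.auto = False
        merged[item.criterion] = item
    return sorted(merged.values(), key=lambda it: it.criterion)


def classify(evidence, rubric: Rubric) -> Classification:
    """Sum evidence points and map the total onto the five-tier bands."""
    total = round(sum(item.points for item in evidence), 10)
    bands = rubric.bands
    if total >= bands["pathogenic_min"]:
        category = Category.PATHOGENIC
    elif total >= bands["likely_pathogenic_min"]:
        category = Category.LIKELY_PATHOGENIC
    elif total > bands["likely_benign_max"]:
        category = Category.VUS
    elif total > bands["benign_max"]:
        category = Category.LIKELY_BENIGN
    else:
        category = Category.BENIGN
    return Classification(total=total, category=category, evidence=list(evidence))


def interpret(cnv: CnvCall, resources: ResourceBundle, rubric: Rubric | None = None,
              user_evidence=()) -> tuple[Classification, list]:
    """Full interpretation of one CNV: sections 1–4, user merge, classification.

    Returns the classification and one report row per evidence item
    (criterion, points, rationale, provenance).
    """
    rubric = rubric or Rubric.load()
    items = [evaluate_section1(cnv, resources, rubric)]
    if cnv.type is CnvType.DEL:
        items.extend(evaluate_section2_loss(cnv, resources, rubric))
    else:
        items.extend(evaluate_section2_gain(cnv, resources, rubric))
    items.append(evaluate_section3(cnv, resources, rubric))
    freq_item = evaluate_section4_frequency(cnv, resources, rubric)
    if freq_item is not None:
        items.append(freq_item)
    items = merge_user_evidence(items, list(user_evidence), rubric)
    classification = classify(items, rubric)
    rows = [{
        "cnv": str(cnv.interval), "type": cnv.type.value,
        "criterion": item.criterion, "points": item.points,
        "rationale": item.rationale,
        "provenance": "auto" if item.auto else "user",
    } for item in classification.evidence]
    rows.append({
        "cnv": str(cnv.interval), "type": cnv.type.value,
        "criterion": "TOTAL", "points": classification.total,
        "rationale": classification.category.value, "provenance": "summary",
    })
    return classification, rows
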