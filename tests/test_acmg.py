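"""Semiquantitative scoring: evidence sections, PVS1 tree, classification."""

import pytest

from cnvcurate import acmg_engine as ae
from cnvcurate.intervals import CnvCall, CnvType, GenomicInterval


def cnv(start, end, cnv_type=CnvType.DEL, chrom="1"):
    return CnvCall(interval=GenomicInterval(chrom, start, end),
                   type=cnv_type, caller="test")


# ---------------------------------------------------------------------------
# section 1

def test_section1_gene_content(resources, rubric):
    item = ae.evaluate_section1(cnv(990_000, 1_060_000), resources, rubric)
    assert item.criterion == "L1A" and item.points == 0.0


def test_section1_intergenic(resources, rubric):
    item = ae.evaluate_section1(cnv(9_000_000, 9_100_000), resources, rubric)
    assert item.criterion == "L1B"


def test_section1_dosage_region_counts_as_element(resources, rubric):
    # gap in genes but inside the benign-gain region
    item = ae.evaluate_section1(cnv(7_600_000, 7_650_000, CnvType.DUP),
                                resources, rubric)
    assert item.criterion == "G1A"


# ---------------------------------------------------------------------------
# section 2, loss

def test_full_hi_gene_deletion_scores_2a(resources, rubric):
    items = ae.evaluate_section2_loss(cnv(990_000, 1_060_000), resources, rubric)
    assert [(i.criterion, i.points) for i in items] == [("L2A", 1.0)]


def test_benign_loss_containment_scores_2f(resources, rubric):
    # inside BLREG1 (7,000,000-7,200,000), covering only BLGENE1
    items = ae.evaluate_section2_loss(cnv(7_040_000, 7_070_000), resources, rubric)
    assert [(i.criterion, i.points) for i in items] == [("L2F", -1.0)]


def test_predicted_hi_only_scores_2h(resources, rubric):
    # PREDHI1 at 4,500,000-4,510,000: constrained but not ClinGen-curated
    items = ae.evaluate_section2_loss(cnv(4_495_000, 4_515_000), resources, rubric)
    assert [(i.criterion, i.points) for i in items] == [("L2H", 0.15)]


def test_hi_region_partial_overlap_scores_2b(resources, rubric):
    items = ae.evaluate_section2_loss(cnv(5_990_000, 6_050_000), resources, rubric)
    assert [i.criterion for i in items] == ["L2B"]


def test_no_dosage_evidence_for_plain_gene(resources, rubric):
    assert ae.evaluate_section2_loss(cnv(5_000_000, 5_012_000),
                                     resources, rubric) == []


def test_intragenic_hi_deletion_routed_through_pvs1(resources, rubric):
    # exon-2 deletion inside HIGENE1: frameshift, NMD, LoF gene -> 0.9
    items = ae.evaluate_section2_loss(cnv(1_009_950, 1_010_150), resources, rubric)
    assert [(i.criterion, i.points) for i in items] == [("L2E", 0.9)]
    assert "NMD" in items[0].rationale


# ---------------------------------------------------------------------------
# PVS1 tree

def test_pvs1_frameshift_nmd_lof_gene_very_strong(resources):
    gene = resources.genes["HIGENE1"]
    result = ae.assess_pvs1_loss(cnv(1_009_950, 1_010_150), gene,
                                 resources.variants_in_gene("HIGENE1"))
    assert result.strength is ae.Pvs1Strength.VERY_STRONG


def test_pvs1_frameshift_nmd_without_lof_mechanism_steps_down(resources):
    gene = resources.genes["HIGENE1"]
    result = ae.assess_pvs1_loss(cnv(1_009_950, 1_010_150), gene, ())
    assert result.strength is ae.Pvs1Strength.MODERATE


def test_pvs1_small_inframe_deletion_moderate(resources):
    """A 99 bp in-frame exon removing ~4% of the protein, no curated variants."""
    gene = resources.genes["HIGENE1"]
    result = ae.assess_pvs1_loss(cnv(1_019_950, 1_020_120), gene, ())
    assert result.strength is ae.Pvs1Strength.MODERATE
    assert any("in-frame" in step for step in result.path)


def test_pvs1_inframe_with_pathogenic_variant_in_region_strong(resources):
    gene = resources.genes["HIGENE1"]
    result = ae.assess_pvs1_loss(cnv(1_019_950, 1_020_120), gene,
                                 resources.variants_in_gene("HIGENE1"))
    assert result.strength is ae.Pvs1Strength.STRONG


def test_pvs1_large_inframe_deletion_strong(resources):
    # exons 2+3+4: 100+99+150 = 349 coding bases, in-frame impossible;
    # use exon 4 alone (150, in-frame) which is 6% -> moderate, then a
    # larger span removing exons 2-4 (349, frameshift escape check):
    gene = resources.genes["HIGENE1"]
    result = ae.assess_pvs1_loss(cnv(1_029_950, 1_030_200), gene, ())
    assert result.strength is ae.Pvs1Strength.MODERATE
    # removing the last-exon coding chunk (2000 nt, >10%, in-frame, no NMD)
    result = ae.assess_pvs1_loss(cnv(1_039_950, 1_042_050), gene, ())
    assert result.strength is ae.Pvs1Strength.STRONG


def test_pvs1_intronic_deletion_none(resources):
    gene = resources.genes["HIGENE1"]
    result = ae.assess_pvs1_loss(cnv(1_005_000, 1_006_000), gene, ())
    assert result.strength is ae.Pvs1Strength.NONE


def test_pvs1_gene_without_cds_none(resources):
    import dataclasses
    gene = resources.genes["VUSGENE"]
    model = dataclasses.replace(gene.exon_model, cds_start=5_000_000,
                                cds_end=5_000_000)
    bare = dataclasses.replace(gene, exon_model=model)
    result = ae.assess_pvs1_loss(cnv(5_000_000, 5_002_000), bare, ())
    assert result.strength is ae.Pvs1Strength.NONE


# ---------------------------------------------------------------------------
# section 2, gain

def test_full_ts_gene_duplication_scores_2a(resources, rubric):
    items = ae.evaluate_section2_gain(cnv(1_990_000, 2_050_000, CnvType.DUP),
                                      resources, rubric)
    assert [(i.criterion, i.points) for i in items] == [("G2A", 1.0)]


def test_benign_gain_containment(resources, rubric):
    items = ae.evaluate_section2_gain(cnv(7_550_000, 7_600_000, CnvType.DUP),
                                      resources, rubric)
    assert [(i.criterion, i.points) for i in items] == [("G2C", -1.0)]


def test_intragenic_dup_conservative_zero(resources, rubric):
    items = ae.evaluate_section2_gain(cnv(1_005_000, 1_010_050, CnvType.DUP),
                                      resources, rubric)
    assert [(i.criterion, i.points) for i in items] == [("G2I", 0.0)]
    assert "unknown" in items[0].rationale


def test_loss_criteria_never_fire_for_dup(resources, rubric):
    classification, _ = ae.interpret(cnv(990_000, 1_060_000, CnvType.DUP),
                                     resources, rubric)
    assert all(not item.criterion.startswith("L")
               for item in classification.evidence)


# ---------------------------------------------------------------------------
# sections 3 and 4

@pytest.mark.parametrize("n_genes,cnv_type,expected,points", [
    (10, CnvType.DEL, "L3A", 0.0),
    (30, CnvType.DEL, "L3B", 0.45),
    (35, CnvType.DEL, "L3C", 0.9),
    (10, CnvType.DUP, "G3A", 0.0),
    (40, CnvType.DUP, "G3B", 0.45),
])
def test_section3_gene_count_bands(resources, rubric, n_genes, cnv_type,
                                   expected, points):
    # chromosome-2 cluster: gene i spans 1,000,000+20,000*i .. +10,000
    end = 1_000_000 + (n_genes - 1) * 20_000 + 10_000
    item = ae.evaluate_section3(cnv(1_000_000, end, cnv_type, chrom="2"),
                                resources, rubric)
    assert (item.criterion, item.points) == (expected, points)
    assert str(n_genes) in item.rationale


def test_section4_common_population_cnv(resources, rubric):
    item = ae.evaluate_section4_frequency(cnv(8_000_000, 8_100_000),
                                          resources, rubric)
    assert item.criterion == "L4O" and item.points == -1.0


def test_section4_rare_or_absent_gives_no_item(resources, rubric):
    # same interval as DUP: only DEL population entries exist there
    assert ae.evaluate_section4_frequency(
        cnv(8_000_000, 8_100_000, CnvType.DUP), resources, rubric) is None
    assert ae.evaluate_section4_frequency(
        cnv(5_000_000, 5_012_000), resources, rubric) is None


# ---------------------------------------------------------------------------
# user evidence and classification

def test_merge_user_evidence_union_and_override(rubric):
    auto = [ae.EvidenceItem("L2H", 0.15, "auto")]
    user = [ae.EvidenceItem("5A", 0.45, "de novo", auto=False)]
    merged = ae.merge_user_evidence(auto, user, rubric)
    assert {i.criterion for i in merged} == {"L2H", "5A"}
    override = [ae.EvidenceItem("L2H", 0.0, "manual review", auto=False)]
    merged = ae.merge_user_evidence(auto, override, rubric)
    item = next(i for i in merged if i.criterion == "L2H")
    assert item.points == 0.0 and not item.auto
    assert "overrides" in item.rationale


def test_user_evidence_out_of_range_rejected(rubric):
    with pytest.raises(ValueError, match="outside"):
        ae.merge_user_evidence([], [ae.EvidenceItem("5A", 9.0, "bad")], rubric)
    with pytest.raises(KeyError):
        ae.merge_user_evidence([], [ae.EvidenceItem("NOPE", 0.1, "bad")], rubric)


BAND_CASES = [(-1.0, "Benign"), (-0.99, "Benign"), (-0.98, "Likely benign"),
              (-0.90, "Likely benign"), (-0.89, "VUS"), (0.0, "VUS"),
              (0.89, "VUS"), (0.90, "Likely pathogenic"),
              (0.98, "Likely pathogenic"), (0.99, "Pathogenic"),
              (1.0, "Pathogenic")]


@pytest.mark.parametrize("total,expected", BAND_CASES)
def test_classification_bands(rubric, total, expected):
    evidence = [ae.EvidenceItem("5D", 0.0, "edge-case total")]
    evidence[0].points = total  # direct total injection for band check
    result = ae.classify(evidence, rubric)
    assert result.category.value == expected
    assert result.total == pytest.approx(total)


def test_positive_user_item_never_moves_toward_benign(resources, rubric):
    order = ["Benign", "Likely benign", "VUS", "Likely pathogenic", "Pathogenic"]
    base, _ = ae.interpret(cnv(5_000_000, 5_012_000), resources, rubric)
    boosted, _ = ae.interpret(cnv(5_000_000, 5_012_000), resources, rubric,
                              user_evidence=[ae.EvidenceItem("5A", 0.45, "de novo")])
    assert order.index(boosted.category.value) >= order.index(base.category.value)
    lowered, _ = ae.interpret(cnv(5_000_000, 5_012_000), resources, rubric,
                              user_evidence=[ae.EvidenceItem("5F", -0.45, "inherited")])
    assert order.index(lowered.category.value) <= order.index(base.category.value)


def test_interpret_deterministic(resources, rubric):
    first = ae.interpret(cnv(990_000, 1_060_000), resources, rubric)
    second = ae.interpret(cnv(990_000, 1_060_000), resources, rubric)
    assert first[0].total == second[0].total
    assert first[1] == second[1]


def test_evidence_points_within_rubric_ranges(resources, rubric):
    for case in [cnv(990_000, 1_060_000), cnv(7_550_000, 7_600_000, CnvType.DUP),
                 cnv(1_009_950, 1_010_150), cnv(8_000_000, 8_100_000)]:
        classification, _ = ae.interpret(case, resources, rubric)
        for item in classification.evidence:
            meta = rubric.criteria[item.criterion]
            assert meta["min"] <= item.points <= meta["max"]


def test_report_rows_include_summary(resources, rubric):
    classification, rows = ae.interpret(cnv(990_000, 1_060_000), resources, rubric)
    assert rows[-1]["criterion"] == "TOTAL"
    assert rows[-1]["rationale"] == classification.category.value
    assert len(rows) == len(classification.evidence) + 1
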