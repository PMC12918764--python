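"""Annotation bundle loading and the queries the scoring engine relies on."""

import pytest

from cnvcurate import annotation_resources as ar
from cnvcurate import fixtures_synthetic as fx
from cnvcurate.intervals import CnvType, GenomicInterval
from cnvcurate.oracles import oracle_gene_overlap, oracle_predicted_hi


def iv(start, end, chrom="1"):
    return GenomicInterval(chrom, start, end)


def test_toy_bundle_loads(resources):
    assert len(resources.genes) > 30
    assert len(resources.dosage_regions) == 4
    assert len(resources.curated_variants) == 5
    assert len(resources.population_cnvs) == 4


def test_missing_table_and_column_errors(tmp_path):
    with pytest.raises(ar.ResourceLoadError, match="genes.tsv"):
        ar.load_resources(tmp_path)
    bundle = fx.generate_resource_bundle(tmp_path / "bundle")
    genes = (bundle / "genes.tsv").read_text().splitlines()
    header = genes[1].split("\t")
    header.remove("pLI")
    genes[1] = "\t".join(header)
    # drop the pLI column values too
    (bundle / "genes.tsv").write_text("\n".join(
        [genes[0], genes[1]] + ["\t".join(l.split("\t")[:16]) for l in genes[2:]]))
    with pytest.raises(ar.ResourceLoadError, match="pLI"):
        ar.load_resources(bundle)


def test_schema_version_line_required(tmp_path):
    bundle = fx.generate_resource_bundle(tmp_path / "bundle")
    text = (bundle / "genes.tsv").read_text().splitlines()
    (bundle / "genes.tsv").write_text("\n".join(text[1:]))
    with pytest.raises(ar.ResourceLoadError, match="bundle-v1"):
        ar.load_resources(bundle)


def test_empty_population_table_is_valid(tmp_path):
    bundle = fx.generate_resource_bundle(tmp_path / "bundle")
    lines = (bundle / "population_cnvs.tsv").read_text().splitlines()[:2]
    (bundle / "population_cnvs.tsv").write_text("\n".join(lines) + "\n")
    resources = ar.load_resources(bundle)
    af, source = resources.max_population_frequency(
        iv(8_000_000, 8_100_000), CnvType.DEL)
    assert af is None and source is None


def test_overlap_kinds(resources):
    gene = resources.genes["HIGENE1"]  # 1:1,000,000-1,050,000, + strand
    kinds = dict(resources.overlapping_genes(iv(990_000, 1_060_000)))
    assert kinds[gene] == "complete"
    kinds = dict(resources.overlapping_genes(iv(1_005_000, 1_006_000)))
    assert kinds[gene] == "internal"
    kinds = dict(resources.overlapping_genes(iv(990_000, 1_010_000)))
    assert kinds[gene] == "partial_5prime"
    kinds = dict(resources.overlapping_genes(iv(1_040_000, 1_060_000)))
    assert kinds[gene] == "partial_3prime"


def test_overlap_strand_mapping(tmp_path):
    """On a minus-strand gene, covering the genomic left end hits the 3' end."""
    bundle = fx.generate_resource_bundle(tmp_path / "bundle")
    lines = (bundle / "genes.tsv").read_text().splitlines()
    out = []
    for line in lines:
        fields = line.split("\t")
        if fields and fields[0] == "VUSGENE":
            fields[4] = "-"
        out.append("\t".join(fields))
    (bundle / "genes.tsv").write_text("\n".join(out) + "\n")
    resources = ar.load_resources(bundle)
    gene = resources.genes["VUSGENE"]  # 5,000,000-5,010,000 now minus strand
    kinds = dict(resources.overlapping_genes(iv(4_990_000, 5_005_000)))
    assert kinds[gene] == "partial_3prime"


def test_overlapping_genes_match_brute_force(resources, bundle_answers):
    gene_dicts = [{"symbol": g.symbol, "chrom": g.interval.chrom,
                   "start": g.interval.start, "end": g.interval.end}
                  for g in resources.genes.values()]
    for name, probe in bundle_answers["count_probes"].items():
        interval = iv(probe[1], probe[2], probe[0])
        got = sorted(g.symbol for g, _ in resources.overlapping_genes(interval))
        assert got == oracle_gene_overlap(tuple(probe), gene_dicts)
        assert got == bundle_answers["overlap_symbols"][name]


def test_gene_count_family_collapsing(resources, bundle_answers):
    """No family: 5; family w/o disease collapses 5 to 3; with disease: 5."""
    probes = bundle_answers["count_probes"]
    for name, expected in bundle_answers["gene_counts"].items():
        probe = probes[name]
        assert resources.count_genes(iv(probe[1], probe[2], probe[0])) == expected
    assert bundle_answers["gene_counts"]["no_family"] == 5
    assert bundle_answers["gene_counts"]["family_without_disease"] == 3
    assert bundle_answers["gene_counts"]["family_with_disease"] == 5


def test_count_never_exceeds_overlap(resources):
    for probe in (iv(0, 10_000_000), iv(1_000_000, 2_000_000, "2"),
                  iv(2_900_000, 3_200_000)):
        count = resources.count_genes(probe)
        assert count <= len(resources.overlapping_genes(probe))


def test_predicted_hi_boundary_corners(resources, bundle_answers):
    """Eight corners around (pLI 0.9, o/e 0.35, HI 10): >=, <, <= as printed."""
    corners = bundle_answers["predicted_hi"]
    assert len(corners) == 8 and sum(corners.values()) == 1
    for symbol, expected in corners.items():
        gene = resources.genes[symbol]
        assert ar.predicted_hi(gene) is expected, symbol
        assert ar.predicted_hi(gene) == oracle_predicted_hi(
            gene.pli, gene.oe_upper, gene.hi_index)


def test_predicted_hi_null_metrics_false(resources):
    assert not ar.predicted_hi(resources.genes["VUSGENE"])


def test_predicted_hi_monotone(resources):
    base = resources.genes["CONS_0p9_0p34_10"]
    assert ar.predicted_hi(base)
    import dataclasses
    better = dataclasses.replace(base, pli=0.99, oe_upper=0.01, hi_index=1.0)
    assert ar.predicted_hi(better)


def test_dosage_hits_type_routing(resources):
    del_hits = resources.dosage_hits(iv(990_000, 1_060_000), CnvType.DEL)
    assert any(isinstance(el, ar.GeneRecord) and el.symbol == "HIGENE1"
               for el, _ in del_hits)
    dup_hits = resources.dosage_hits(iv(990_000, 1_060_000), CnvType.DUP)
    assert dup_hits == []  # HI-only gene is not a DUP dosage hit
    ts_hits = resources.dosage_hits(iv(1_990_000, 2_050_000), CnvType.DUP)
    assert any(isinstance(el, ar.GeneRecord) and el.symbol == "TSGENE1"
               for el, _ in ts_hits)


def test_dosage_hit_fractions(resources):
    # full coverage of the HI region
    hits = resources.dosage_hits(iv(5_990_000, 6_110_000), CnvType.DEL)
    region_hits = [(el, f) for el, f in hits if isinstance(el, ar.DosageRegion)]
    assert region_hits and region_hits[0][1] == pytest.approx(1.0)
    # half coverage: HI region is 6,000,000-6,100,000
    hits = resources.dosage_hits(iv(6_000_000, 6_050_000), CnvType.DEL)
    assert hits[0][1] == pytest.approx(0.5)


def test_population_frequency_max_and_type(resources):
    af, source = resources.max_population_frequency(
        iv(8_000_000, 8_100_000), CnvType.DEL)
    assert af == pytest.approx(0.02)
    assert source == "gnomAD_controls"
    af, _ = resources.max_population_frequency(
        iv(8_000_000, 8_100_000), CnvType.DUP)
    assert af is None
    af, source = resources.max_population_frequency(
        iv(7_550_000, 7_600_000), CnvType.DUP)
    assert af == pytest.approx(0.05)


def test_reload_deterministic(tmp_path, resources):
    bundle = fx.generate_resource_bundle(tmp_path / "again")
    reloaded = ar.load_resources(bundle)
    probe = iv(2_975_000, 3_171_000)
    assert reloaded.count_genes(probe) == resources.count_genes(probe)
    assert [g.symbol for g, _ in reloaded.overlapping_genes(probe)] == \
        [g.symbol for g, _ in resources.overlapping_genes(probe)]


def test_exon_model_coding_arithmetic(resources):
    model = resources.genes["HIGENE1"].exon_model
    # coding pieces 100+100+99+150+2000 = 2449
    assert model.coding_length == 2449
    assert model.nmd_boundary_offset() == 449 - 50
    # deleting exon 2 removes 100 coding bases starting at offset 100
    removed, min_offset = model.deleted_coding_offsets(iv(1_009_950, 1_010_150))
    assert (removed, min_offset) == (100, 100)
    # intronic interval removes nothing
    assert model.deleted_coding_offsets(iv(1_005_000, 1_006_000)) == (0, None)
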