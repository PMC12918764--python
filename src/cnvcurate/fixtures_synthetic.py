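"""Synthetic fixtures: caller VCFs, annotation bundles and merge scenarios.

Everything the pipeline consumes can be fabricated here with known
expected outputs, so the whole package is testable without downloading a
single external resource. Expected outcomes are computed at generation
time by the deliberately naive reference implementations in
:mod:`cnvcurate.oracles` — literal rule transcriptions and quadratic
scans that share no code with the production modules.

The toy genome is two 10 Mb chromosomes (merge scenarios spread over
eight) — large enough to separate every planted feature, small enough
that all fixtures generate in well under a second.

Layout of the planted annotation bundle (all coordinates 0-based):

* ``HIGENE1``  1:1,000,000–1,050,000, ClinGen HI 3, five exons designed so
  single-exon deletions exercise every PVS1 branch (frameshift+NMD,
  in-frame small, etc.).
* ``TSGENE1``  1:2,000,000–2,040,000, ClinGen TS 3.
* families ``FAMA`` (three members, none disease-associated — collapses)
  and ``FAMB`` (three members, one disease-associated — does not).
* eight constraint-corner genes straddling the predicted-HI cut-offs
  (pLI 0.9 / o-e upper 0.35 / HI index 10) plus one clearly constrained
  gene ``PREDHI1``.
* curated HI / TS / benign-loss / benign-gain regions; population CNVs at
  allele frequencies 0.0001, 0.001, 0.02 and 0.05.
* a 40-gene cluster on chromosome 2 for the gene-number bands.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from cnvcurate import oracles

CHROM_SIZES = {"1": 10_000_000, "2": 10_000_000}


@dataclass
class FixtureSpec:
    seed: int = 0
    chrom_sizes: dict = field(default_factory=lambda: dict(CHROM_SIZES))


# ---------------------------------------------------------------------------
# plain-text VCF writing (independent of the package's pysam-based writer,
# so reader tests exercise files the reader did not itself produce)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=cnvcurate-fixtures
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
{metric_lines}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=FT,Number=1,Type=String,Description="Genotype filter">
##FILTER=<ID=LowQual,Description="Low quality">
##FILTER=<ID=NO_ASSEMBLY,Description="No assembly">
{contig_lines}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf_text(path, records, sample="SAMPLE1",
                   chrom_sizes=None) -> None:
    """Write record dicts (see oracles module) as a symbolic-allele VCF."""
    chrom_sizes = chrom_sizes or CHROM_SIZES
    metric_names = sorted({k for r in records for k in r.get("metrics", {})})
    metric_lines = "".join(
        f'##INFO=<ID={m},Number=1,Type=Float,Description="metric">\n'
        for m in metric_names)
    chroms = sorted({r["chrom"] for r in records} | set(chrom_sizes))
    contig_lines = "".join(
        f"##contig=<ID={c},length={chrom_sizes.get(c, 100_000_000)}>\n"
        for c in chroms)
    lines = [_VCF_HEADER.format(metric_lines=metric_lines,
                                contig_lines=contig_lines, sample=sample)]
    for rec in sorted(records, key=lambda r: (r["chrom"], r["start"])):
        info = [f"SVTYPE={rec['type']}", f"END={rec['end']}"]
        svlen = rec["end"] - rec["start"]
        info.append(f"SVLEN={svlen if rec['type'] == 'DUP' else -svlen}")
        for name, value in sorted(rec.get("metrics", {}).items()):
            info.append(f"{name}={value:g}")
        qual = "." if rec.get("qual") is None else f"{rec['qual']:g}"
        filters = ";".join(rec.get("filters") or ["PASS"])
        fmt_keys, fmt_vals = ["GT"], [rec.get("gt") or "./."]
        if rec.get("ft") is not None:
            fmt_keys.append("FT")
            fmt_vals.append(rec["ft"])
        lines.append("\t".join([
            rec["chrom"], str(rec["start"] + 1), rec.get("id", "."), "N",
            f"<{rec['type']}>", qual, filters, ";".join(info),
            ":".join(fmt_keys), ":".join(fmt_vals)]) + "\n")
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# caller filter fixtures

def _base_interval(rng, index, cnv_type="DEL"):
    start = 100_000 + index * 10_000
    return {"chrom": "1", "start": start, "end": start + 5_000, "type": cnv_type}


def caller_filter_records(seed: int = 0) -> list:
    """Planted per-caller records straddling every printed threshold.

    Returns record dicts with ``kept``/``reasons`` filled in by the
    rule-transcription oracle.
    """
    rng = random.Random(seed)
    records = []

    def add(caller, cnv_type="DEL", **kw):
        rec = _base_interval(rng, len(records), cnv_type)
        rec.update({"caller": caller, "id": f"{caller}_{len(records):03d}"}, **kw)
        kept, reasons = oracles.oracle_filter(rec)
        rec["kept"], rec["reasons"] = kept, reasons
        records.append(rec)

    # CNVpytor: each metric at, below and above its threshold
    for p1 in (0.01, 0.05, 0.06):
        for q0 in (0.2, 0.9, 0.95):
            for rd in (0.4, 0.75, 1.0, 1.25, 1.5):
                add("cnvpytor", metrics={"pytorP1": p1, "Q0": q0, "pytorRD": rd})
    # ControlFREEC
    for w in (0.01, 0.05, 0.06):
        for ks in (0.01, 0.05, 0.06):
            add("controlfreec", metrics={"W": w, "KS": ks})
    # delly / Manta PASS + genotype rule
    for caller in ("delly", "manta"):
        for filters in (["PASS"], ["LowQual"]):
            for ft in ("PASS", "LowGQ", None):
                for gt in ("0/1", "0/0", "1/1"):
                    add(caller, filters=list(filters), ft=ft, gt=gt, qual=100)
    # lumpy QUAL boundary
    for qual in (100, 119, 120, 121, 500):
        add("lumpy", qual=qual, gt="0/1")
    # Wham
    for cw in (0.19, 0.2, 0.3):
        for tf in (2, 3, 10):
            add("wham", "DEL", metrics={"max_CW": cw, "TF": tf, "U": 5})
        for u in (1, 2, 5):
            add("wham", "DUP", metrics={"max_CW": cw, "TF": 5, "U": u})
    # GRIDSS
    add("gridss", filters=["PASS"], qual=200, gt="0/1")
    add("gridss", filters=["NO_ASSEMBLY"], qual=200, gt="0/1")
    add("gridss", filters=["NO_ASSEMBLY", "LowQual"], qual=200, gt="0/1")
    # ExomeDepth
    for bf in (14, 15, 20):
        for ratio in (0.5, 0.8, 0.81):
            add("exomedepth", "DEL", metrics={"BF": bf, "reads_ratio": ratio})
        for ratio in (1.09, 1.1, 1.5):
            add("exomedepth", "DUP", metrics={"BF": bf, "reads_ratio": ratio})
    # GATK4: every formula branch, QS one below / at / one above threshold
    for nt in (1, 10, 40, 70, 150):
        for cn in (0, 1):
            t = oracles.oracle_gatk4_threshold("DEL", cn, nt)
            for qs in (t - 1, t, t + 1):
                add("gatk4", "DEL", metrics={"QS": qs, "CN": cn, "nt": nt})
        t = oracles.oracle_gatk4_threshold("DUP", -1, nt)
        for qs in (t - 1, t, t + 1):
            add("gatk4", "DUP", metrics={"QS": qs, "CN": 3, "nt": nt})
    # pass-through caller
    for _ in range(4):
        add("cn.mops", "DEL" if rng.random() < 0.5 else "DUP")
    return records


def generate_caller_vcfs(out_dir, seed: int = 0) -> tuple[dict, list]:
    """Write one VCF per caller plus the expected-outcome table.

    Returns ``(paths by caller, expected record dicts)``; the expected
    table is also written as ``expected_filters.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = caller_filter_records(seed)
    paths = {}
    for caller in sorted({r["caller"] for r in records}):
        path = out_dir / f"{caller}.vcf"
        write_vcf_text(path, [r for r in records if r["caller"] == caller])
        paths[caller] = path
    (out_dir / "expected_filters.json").write_text(
        json.dumps(records, indent=1, default=str))
    return paths, records


# ---------------------------------------------------------------------------
# annotation resource bundle

def _gene_row(symbol, chrom, start, end, strand="+", exons=None, cds=None,
              mane=True, family="", disease=False, pli="", oe="", hi="",
              clingen_hi="", clingen_ts=""):
    if exons is None:
        exons = [(start, end)]
    if cds is None:
        cds = (exons[0][0], exons[-1][1])
    return {
        "symbol": symbol, "chrom": chrom, "start": start, "end": end,
        "strand": strand,
        "exon_starts": ",".join(str(s) for s, _ in exons),
        "exon_ends": ",".join(str(e) for _, e in exons),
        "cds_start": cds[0], "cds_end": cds[1],
        "mane": int(mane), "family": family, "disease_assoc": int(disease),
        "pLI": pli, "oe_upper": oe, "hi_index": hi,
        "clingen_hi": clingen_hi, "clingen_ts": clingen_ts,
    }


# HIGENE1 exon plan (plus strand). Coding pieces: 100, 100, 99, 150, 2000 nt
# (total 2449); NMD boundary = 449 - 50 = 399 coding nt.
HIGENE1_EXONS = [(1_000_000, 1_000_200), (1_010_000, 1_010_100),
                 (1_020_000, 1_020_099), (1_030_000, 1_030_150),
                 (1_040_000, 1_050_000)]
HIGENE1_CDS = (1_000_100, 1_042_000)


def bundle_tables(seed: int = 0) -> dict:
    """All four resource tables as row-dict lists, plus probe expectations."""
    genes = [
        _gene_row("HIGENE1", "1", 1_000_000, 1_050_000, exons=HIGENE1_EXONS,
                  cds=HIGENE1_CDS, disease=True, pli=0.99, oe=0.1, hi=2,
                  clingen_hi=3),
        _gene_row("NBR1", "1", 996_000, 998_000),
        _gene_row("NBR2", "1", 1_052_000, 1_054_000),
        _gene_row("TSGENE1", "1", 2_000_000, 2_040_000, disease=True,
                  clingen_ts=3),
        # families: FAMA collapses, FAMB (one disease member) does not
        _gene_row("SOLO0", "1", 2_980_000, 2_990_000),
        _gene_row("FAMA1", "1", 3_000_000, 3_010_000, family="FAMA"),
        _gene_row("FAMA2", "1", 3_020_000, 3_030_000, family="FAMA"),
        _gene_row("FAMA3", "1", 3_040_000, 3_050_000, family="FAMA"),
        _gene_row("SOLO1", "1", 3_060_000, 3_070_000),
        _gene_row("SOLO3", "1", 3_080_000, 3_090_000),
        _gene_row("FAMB1", "1", 3_100_000, 3_110_000, family="FAMB"),
        _gene_row("FAMB2", "1", 3_120_000, 3_130_000, family="FAMB",
                  disease=True),
        _gene_row("FAMB3", "1", 3_140_000, 3_150_000, family="FAMB"),
        _gene_row("SOLO2", "1", 3_160_000, 3_170_000),
        _gene_row("PREDHI1", "1", 4_500_000, 4_510_000, pli=0.95, oe=0.2, hi=5),
        _gene_row("VUSGENE", "1", 5_000_000, 5_010_000),
        _gene_row("BLGENE1", "1", 7_050_000, 7_060_000),
    ]
    # constraint corner genes around (pLI 0.9, oe 0.35, HI 10)
    corners = []
    pos = 4_000_000
    for pli in (0.9, 0.89):
        for oe in (0.34, 0.35):
            for hi in (10, 10.5):
                symbol = f"CONS_{pli:g}_{oe:g}_{hi:g}".replace(".", "p")
                corners.append((symbol, pli, oe, hi))
                genes.append(_gene_row(symbol, "1", pos, pos + 10_000,
                                       pli=pli, oe=oe, hi=hi))
                pos += 20_000
    # 40-gene cluster on chromosome 2 for the gene-count bands
    for i in range(40):
        start = 1_000_000 + i * 20_000
        genes.append(_gene_row(f"GC{i + 1:03d}", "2", start, start + 10_000))

    dosage = [
        {"chrom": "1", "start": 6_000_000, "end": 6_100_000,
         "kind": "HI_region", "label": "HIREG1"},
        {"chrom": "1", "start": 6_200_000, "end": 6_300_000,
         "kind": "TS_region", "label": "TSREG1"},
        {"chrom": "1", "start": 7_000_000, "end": 7_200_000,
         "kind": "benign_loss_region", "label": "BLREG1"},
        {"chrom": "1", "start": 7_500_000, "end": 7_700_000,
         "kind": "benign_gain_region", "label": "BGREG1"},
    ]
    variants = [
        # null pathogenic variants establishing HIGENE1's LoF mechanism
        {"gene": "HIGENE1", "position": 1_010_050, "consequence": "nonsense",
         "pathogenicity": "pathogenic", "in_last_exon": 0},
        {"gene": "HIGENE1", "position": 1_000_150, "consequence": "frameshift",
         "pathogenicity": "pathogenic", "in_last_exon": 0},
        {"gene": "HIGENE1", "position": 1_030_050, "consequence": "splicing",
         "pathogenicity": "pathogenic", "in_last_exon": 0},
        # last-exon pathogenic variant
        {"gene": "HIGENE1", "position": 1_040_100, "consequence": "nonsense",
         "pathogenicity": "pathogenic", "in_last_exon": 1},
        {"gene": "TSGENE1", "position": 2_010_000, "consequence": "other",
         "pathogenicity": "benign", "in_last_exon": 0},
    ]
    population = [
        {"chrom": "1", "start": 7_550_000, "end": 7_600_000, "type": "DUP",
         "af": 0.05, "source": "gnomAD_controls"},
        {"chrom": "1", "start": 8_000_000, "end": 8_100_000, "type": "DEL",
         "af": 0.001, "source": "DGV"},
        {"chrom": "1", "start": 8_000_500, "end": 8_100_500, "type": "DEL",
         "af": 0.02, "source": "gnomAD_controls"},
        {"chrom": "1", "start": 8_001_000, "end": 8_099_000, "type": "DEL",
         "af": 0.0001, "source": "DECIPHER"},
    ]

    gene_dicts = [{"symbol": g["symbol"], "chrom": g["chrom"],
                   "start": g["start"], "end": g["end"],
                   "family": g["family"] or None,
                   "disease_assoc": bool(g["disease_assoc"])} for g in genes]
    count_probes = {
        # five singleton genes, no collapsing
        "no_family": ("1", 4_000_000, 4_090_000),
        # SOLO0 + FAMA1-3 + SOLO1: family of 3 without disease collapses
        "family_without_disease": ("1", 2_975_000, 3_071_000),
        # SOLO3 + FAMB1-3 + SOLO2: disease member blocks collapsing
        "family_with_disease": ("1", 3_075_000, 3_171_000),
    }
    expectations = {
        "predicted_hi": {symbol: oracles.oracle_predicted_hi(pli, oe, hi)
                         for symbol, pli, oe, hi in corners},
        "gene_counts": {name: oracles.oracle_gene_count(probe, gene_dicts)
                        for name, probe in count_probes.items()},
        "count_probes": {name: list(probe)
                         for name, probe in count_probes.items()},
        "overlap_symbols": {name: oracles.oracle_gene_overlap(probe, gene_dicts)
                            for name, probe in count_probes.items()},
    }
    return {"genes": genes, "dosage": dosage, "variants": variants,
            "population": population, "expectations": expectations}


def generate_resource_bundle(out_dir, seed: int = 0) -> Path:
    """Write the toy annotation bundle; expectations land in answers.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = bundle_tables(seed)

    def write_tsv(name, rows, columns):
        lines = ["#cnvcurate-bundle-v1", "\t".join(columns)]
        for row in rows:
            lines.append("\t".join(str(row[c]) for c in columns))
        (out_dir / name).write_text("\n".join(lines) + "\n")

    write_tsv("genes.tsv", tables["genes"],
              ["symbol", "chrom", "start", "end", "strand", "exon_starts",
               "exon_ends", "cds_start", "cds_end", "mane", "family",
               "disease_assoc", "pLI", "oe_upper", "hi_index",
               "clingen_hi", "clingen_ts"])
    write_tsv("dosage_regions.tsv", tables["dosage"],
              ["chrom", "start", "end", "kind", "label"])
    write_tsv("curated_variants.tsv", tables["variants"],
              ["gene", "position", "consequence", "pathogenicity",
               "in_last_exon"])
    write_tsv("population_cnvs.tsv", tables["population"],
              ["chrom", "start", "end", "type", "af", "source"])
    (out_dir / "answers.json").write_text(
        json.dumps(tables["expectations"], indent=1))
    return out_dir


# ---------------------------------------------------------------------------
# golden interpretation cases (hand-traced against the planted bundle)

def golden_cnvs() -> list:
    """Three end-to-end cases with hand-assembled expected evidence.

    Expected totals come from the planted evidence points; the expected
    category is the band oracle's answer for that total.
    """
    cases = [
        {"name": "toy_2A_DEL", "chrom": "1", "start": 995_000, "end": 1_055_000,
         "type": "DEL",
         # 1A (0) + 2A full HI-gene overlap (+1.0) + 3A (3 genes, 0)
         "expected_points": [0.0, 1.0, 0.0]},
        {"name": "toy_benign_DUP", "chrom": "1", "start": 7_550_000,
         "end": 7_600_000, "type": "DUP",
         # 1A via benign region element (0) + 2C benign containment (-1.0)
         # + 3A (0) + 4O common population DUP at AF 0.05 (-1.0)
         "expected_points": [0.0, -1.0, 0.0, -1.0]},
        {"name": "toy_VUS_DEL", "chrom": "1", "start": 5_000_000,
         "end": 5_012_000, "type": "DEL",
         # 1A (0) + no section 2 + 3A (0); no population match
         "expected_points": [0.0, 0.0]},
    ]
    for case in cases:
        total = round(sum(case["expected_points"]), 10)
        case["expected_total"] = total
        case["expected_category"] = oracles.oracle_classification_band(total)
    return cases


def write_golden_caller_vcfs(out_dir, callers=("delly", "lumpy", "cn.mops")):
    """Per-caller VCFs each reporting the three golden CNVs identically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for caller in callers:
        records = [{"chrom": c["chrom"], "start": c["start"], "end": c["end"],
                    "type": c["type"], "caller": caller, "qual": 500,
                    "gt": "0/1", "ft": "PASS", "filters": ["PASS"],
                    "id": c["name"]} for c in golden_cnvs()]
        path = out_dir / f"{caller}.vcf"
        write_vcf_text(path, records)
        paths.append({"caller": caller, "vcf": str(path)})
    return paths


# ---------------------------------------------------------------------------
# merge cluster scenarios

MERGE_CALLER_POOL = ("cnvpytor", "cn.mops", "controlfreec", "delly", "lumpy",
                     "wham")


def generate_cluster_scenario(rng: random.Random, max_events: int = 10) -> dict:
    """One randomized merge scenario with its transitive-closure partition.

    Planted events sit on well-separated loci (2 Mb apart on a chromosome),
    each caller contributes at most one call per event, and perturbations
    fall both within and just beyond the fractional breakpoint-distance
    bound, so some events shatter into singleton clusters.
    """
    max_dist = 0.5
    n_events = rng.randint(3, max_events)
    records = []
    cursors = {str(c): 500_000 for c in range(1, 9)}
    for event_index in range(n_events):
        chrom = str(rng.randint(1, 8))
        length = rng.randint(60, 500_000)
        start = cursors[chrom]
        cursors[chrom] += length + 2_000_000
        cnv_type = rng.choice(("DEL", "DUP"))
        callers = rng.sample(MERGE_CALLER_POOL, rng.randint(1, 5))
        for caller in callers:
            if rng.random() < 0.2:
                # push one endpoint just beyond the allowed offset
                delta = int(max_dist * length) + rng.randint(1000, 5000)
            else:
                delta = rng.randint(0, max(0, int(0.3 * length)))
            sign = rng.choice((-1, 1))
            new_start = max(0, start + sign * delta)
            new_end = max(new_start + 50, start + length + sign * delta // 2)
            records.append({"chrom": chrom, "start": new_start, "end": new_end,
                            "type": cnv_type, "caller": caller,
                            "event": event_index})
    partition = oracles.oracle_cluster_partition(records, max_dist)
    return {"records": records, "max_dist": max_dist,
            "expected_partition": [sorted(group) for group in partition]}


def generate_cluster_scenarios(seed: int = 0, n_scenarios: int = 100) -> list:
    rng = random.Random(seed)
    return [generate_cluster_scenario(rng) for _ in range(n_scenarios)]


# ---------------------------------------------------------------------------
# region-filter fixtures

def generate_region_fixture(seed: int = 0, n_cnvs: int = 200,
                            n_regions: int = 30) -> dict:
    """Random CNVs vs random blacklist regions with all-pairs expectations."""
    rng = random.Random(seed)

    def random_interval():
        chrom = rng.choice(("1", "2"))
        start = rng.randint(0, 9_000_000)
        return (chrom, start, start + rng.randint(100, 500_000))

    cnvs = [random_interval() for _ in range(n_cnvs)]
    regions = [random_interval() for _ in range(n_regions)]
    kept = oracles.oracle_region_filter(cnvs, regions, 0.70)
    return {"cnvs": cnvs, "regions": regions, "threshold": 0.70,
            "expected_kept": kept}


def write_region_beds(out_dir, fixture: dict) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cnv_bed = out_dir / "cnvs.bed"
    region_bed = out_dir / "blacklist.bed"
    cnv_bed.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in fixture["cnvs"]))
    region_bed.write_text("".join(f"{c}\t{s}\t{e}\n"
                                  for c, s, e in fixture["regions"]))
    return cnv_bed, region_bed
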