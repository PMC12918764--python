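"""Deliberately naive reference implementations for fixture expectations.

Everything here works on plain dicts and tuples and re-transcribes each
rule literally — quadratic scans, no interval indexes, no shared code with
the production modules. The fixture generator uses these to compute the
expected outcome of every planted record at generation time, so tests
compare two independent derivations of the same answer.

Record dict shape::

    {"chrom": "1", "start": 0, "end": 1000, "type": "DEL",
     "qual": 130.0, "gt": "0/1", "ft": "PASS", "filters": ["PASS"],
     "metrics": {"pytorP1": 0.01, ...}, "caller": "cnvpytor", "id": "r1"}
"""

from __future__ import annotations


# ---------------------------------------------------------------------------
# caller filter rules, transcribed one inequality at a time

def oracle_filter(rec: dict) -> tuple[bool, list]:
    """(kept, reasons) per the caller's printed rule; pass-through keeps."""
    caller = rec["caller"]
    m = rec.get("metrics", {})
    reasons = []
    if caller == "cnvpytor":
        if m["pytorP1"] > 0.05:
            reasons.append("pytorP1")
        if m["Q0"] > 0.9:
            reasons.append("Q0")
        if m["pytorRD"] > 0.75 and m["pytorRD"] < 1.25:
            reasons.append("pytorRD")
    elif caller == "controlfreec":
        if m["W"] > 0.05:
            reasons.append("W")
        if m["KS"] > 0.05:
            reasons.append("KS")
    elif caller in ("delly", "manta"):
        if rec.get("filters") not in ([], ["PASS"]):
            reasons.append("site_filter")
        if rec.get("ft") is not None and rec["ft"] != "PASS":
            reasons.append("genotype_filter")
        if rec.get("gt") == "0/0":
            reasons.append("hom_ref_genotype")
    elif caller == "lumpy":
        if rec["qual"] < 120:
            reasons.append("quality")
    elif caller == "wham":
        if m["max_CW"] < 0.2:
            reasons.append("max_CW")
        if rec["type"] == "DEL" and m["TF"] < 3:
            reasons.append("TF")
        if rec["type"] == "DUP" and m["U"] < 2:
            reasons.append("U")
    elif caller == "gridss":
        if "NO_ASSEMBLY" in rec.get("filters", []):
            reasons.append("NO_ASSEMBLY")
    elif caller == "exomedepth":
        if m["BF"] < 15:
            reasons.append("BF")
        if rec["type"] == "DEL" and m["reads_ratio"] > 0.8:
            reasons.append("reads_ratio")
        if rec["type"] == "DUP" and m["reads_ratio"] < 1.1:
            reasons.append("reads_ratio")
    elif caller == "gatk4":
        nt = m["nt"]
        if rec["type"] == "DUP":
            t = min(400, max(50, 4 * nt))
            if m["QS"] < t:
                reasons.append("QS")
        elif m["CN"] == 0:
            t = min(1000, max(400, 10 * nt))
            if m["QS"] < t:
                reasons.append("QS")
        elif m["CN"] == 1:
            t = min(1000, max(100, 10 * nt))
            if m["QS"] < t:
                reasons.append("QS")
    return (len(reasons) == 0, reasons)


def oracle_gatk4_threshold(cnv_type: str, cn: int, nt: int) -> float:
    if cnv_type == "DUP":
        return min(400, max(50, 4 * nt))
    return min(1000, max(400, 10 * nt)) if cn == 0 else min(1000, max(100, 10 * nt))


# ---------------------------------------------------------------------------
# merge clustering by explicit transitive closure

def oracle_size_bin(length: int, platform: str = "WGS_LRS") -> str:
    if platform == "WES":
        if length < 10_000:
            return "S"
        return "M" if length < 100_000 else "L"
    if length < 500:
        return "SS"
    if length < 5_000:
        return "S"
    return "M" if length < 100_000 else "L"


def oracle_compatible(a: dict, b: dict, max_dist: float,
                      platform: str = "WGS_LRS") -> bool:
    if a["chrom"] != b["chrom"] or a["type"] != b["type"]:
        return False
    len_a, len_b = a["end"] - a["start"], b["end"] - b["start"]
    if oracle_size_bin(len_a, platform) != oracle_size_bin(len_b, platform):
        return False
    allowed = max_dist * max(len_a, len_b) if max_dist < 1 else max_dist
    return (abs(a["start"] - b["start"]) <= allowed
            and abs(a["end"] - b["end"]) <= allowed)


def oracle_cluster_partition(records: list, max_dist: float,
                             platform: str = "WGS_LRS") -> list:
    """Connected components of the compatibility graph, as index sets."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if oracle_compatible(records[i], records[j], max_dist, platform):
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(groups.values(), key=lambda s: min(s))


# ---------------------------------------------------------------------------
# reciprocal overlap and region filtering, all-pairs

def oracle_reciprocal_overlap(a: tuple, b: tuple) -> float:
    """a, b are (chrom, start, end) tuples."""
    if a[0] != b[0]:
        return 0.0
    o = min(a[2], b[2]) - max(a[1], b[1])
    if o <= 0:
        return 0.0
    return min(o / (a[2] - a[1]), o / (b[2] - b[1]))


def oracle_region_filter(cnvs: list, regions: list, threshold: float) -> list:
    """True per CNV iff kept (no single region reaches the threshold)."""
    kept = []
    for cnv in cnvs:
        removed = any(oracle_reciprocal_overlap(cnv, region) >= threshold
                      for region in regions)
        kept.append(not removed)
    return kept


# ---------------------------------------------------------------------------
# annotation answers

def oracle_gene_overlap(cnv: tuple, genes: list) -> list:
    """Symbols of genes (dicts with chrom/start/end/symbol) touching the CNV."""
    chrom, start, end = cnv
    return sorted(g["symbol"] for g in genes
                  if g["chrom"] == chrom and g["start"] < end and start < g["end"])


def oracle_gene_count(cnv: tuple, genes: list) -> int:
    """Family-collapsed count: families of >=2 overlapped, all non-disease, count 1."""
    overlapped = [g for g in genes
                  if g["chrom"] == cnv[0] and g["start"] < cnv[2] and cnv[1] < g["end"]]
    families: dict = {}
    count = 0
    for g in overlapped:
        if g.get("family"):
            families.setdefault(g["family"], []).append(g)
        else:
            count += 1
    for members in families.values():
        if len(members) >= 2 and not any(m["disease_assoc"] for m in members):
            count += 1
        else:
            count += len(members)
    return count


def oracle_predicted_hi(pli, oe_upper, hi_index) -> bool:
    if pli is None or oe_upper is None or hi_index is None:
        return False
    return pli >= 0.9 and oe_upper < 0.35 and hi_index <= 10


def oracle_classification_band(total: float) -> str:
    if total >= 0.99:
        return "Pathogenic"
    if total >= 0.90:
        return "Likely pathogenic"
    if total >= -0.89:
        return "VUS"
    if total >= -0.98:
        return "Likely benign"
    return "Benign"
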