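"""Reading and writing CNV call sets in VCF, BED and TSV.

One coordinate convention rules the package: 0-based half-open. VCF is
1-based inclusive, so a symbolic-allele record with POS=1001, END=2000
becomes the internal interval [1000, 2000). BED coordinates are passed
through unchanged. Region strings typed by users ("chr11:100-200-DEL")
are read as 1-based inclusive, matching what people expect from a genome
browser, and converted on parse.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pysam

from cnvcurate.intervals import CnvCall, CnvRecordSet, CnvType, GenomicInterval
from cnvcurate.profiles import CallerProfile

log = logging.getLogger(__name__)

_REGION_RE = re.compile(
    r"^\s*(?:chr)?([0-9XYM][0-9T]?)\s*:\s*([0-9,]+)\s*[-–]\s*([0-9,]+)\s*[-–]\s*"
    r"(DEL|DUP|LOSS|GAIN)\s*$", re.IGNORECASE)


class VcfParseError(ValueError):
    pass


def _scalar(value):
    # pysam returns INFO numbers as tuples when Number != 1
    if isinstance(value, tuple):
        value = value[0]
    return value


def _decimal_float(value) -> float:
    """Undo float32 widening of VCF Float fields.

    htslib stores Type=Float in 32 bits, so a printed 0.05 reads back as
    0.05000000074..., which would flip strict-inequality filter boundaries.
    Callers print decimal text; snapping to 6 significant digits recovers
    the printed value exactly for any realistically printed metric.
    """
    return float(f"{float(value):.6g}")


def _record_end(rec) -> int | None:
    """0-based exclusive end from END, else POS + |SVLEN| for DEL/DUP."""
    info = rec.info
    if "END" in info:
        return int(_scalar(info["END"]))
    if "SVLEN" in info:
        svlen = abs(int(_scalar(info["SVLEN"])))
        return rec.start + svlen
    # pysam folds END into rec.stop; trust it when longer than the REF allele
    if rec.stop is not None and rec.stop > rec.start + len(rec.ref or "N"):
        return rec.stop
    return None


def _record_type(rec) -> CnvType | None:
    alts = rec.alts or ()
    for alt in alts:
        if alt in ("<DEL>", "<DUP>") or (alt or "").startswith("<DUP"):
            return CnvType.parse(alt.strip("<>").split(":")[0])
    svtype = rec.info.get("SVTYPE")
    if svtype in ("DEL", "DUP"):
        return CnvType(svtype)
    return None


def read_vcf(path, caller_profile: CallerProfile, sample: str | None = None,
             assembly: str = "GRCh38") -> CnvRecordSet:
    """Load symbolic DEL/DUP records from a caller VCF.

    Non-DEL/DUP records (inversions, breakends, SNVs) and records lacking
    both END and SVLEN are skipped and counted on the returned set's
    ``skipped`` attribute. Only the first sample's genotype is read.
    """
    path = str(path)
    calls: list[CnvCall] = []
    skipped = 0
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        sample_name = sample or (vf.header.samples[0] if vf.header.samples else None)
        for rec in vf:
            cnv_type = _record_type(rec)
            if cnv_type is None:
                skipped += 1
                continue
            end = _record_end(rec)
            if end is None or end <= rec.start:
                skipped += 1
                log.warning("record %s:%s lacks usable END/SVLEN; skipped",
                            rec.chrom, rec.pos)
                continue
            genotype = genotype_filter = None
            if sample_name is not None and sample_name in rec.samples:
                fmt = rec.samples[sample_name]
                gt = fmt.get("GT")
                if gt is not None and any(a is not None for a in gt):
                    genotype = "/".join("." if a is None else str(a) for a in gt)
                ft = fmt.get("FT")
                if ft is not None:
                    genotype_filter = ft if isinstance(ft, str) else str(_scalar(ft))
            metrics = {}
            for name, (where, key) in caller_profile.metrics.items():
                source = rec.info if where == "INFO" else (
                    rec.samples[sample_name] if sample_name else {})
                if key in source:
                    value = _scalar(source[key])
                    if value is not None:
                        metrics[name] = _decimal_float(value)
            calls.append(CnvCall(
                interval=GenomicInterval(rec.chrom, rec.start, end),
                type=cnv_type,
                caller=caller_profile.caller,
                genotype=genotype,
                genotype_filter=genotype_filter,
                filter_status=frozenset(rec.filter.keys()),
                quality=float(rec.qual) if rec.qual is not None else None,
                metrics=metrics,
            ))
    return CnvRecordSet(sample=sample_name or "sample", caller=caller_profile.caller,
                        assembly=assembly, calls=calls, skipped=skipped)


def read_bed(path, caller: str, default_type: CnvType | None = None,
             sample: str = "sample", assembly: str = "GRCh38") -> CnvRecordSet:
    """Load a BED3/BED4 call set; column 4, when present, is DEL or DUP."""
    calls: list[CnvCall] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                skipped += 1
                log.warning("%s:%d: end <= start; record rejected", path, lineno)
                continue
            if len(fields) >= 4 and fields[3].upper() in ("DEL", "DUP", "LOSS", "GAIN"):
                cnv_type = CnvType.parse(fields[3])
            elif default_type is not None:
                cnv_type = default_type
            else:
                raise ValueError(
                    f"{path}:{lineno}: no type column and no default_type given")
            calls.append(CnvCall(interval=GenomicInterval(chrom, start, end),
                                 type=cnv_type, caller=caller))
    return CnvRecordSet(sample=sample, caller=caller, assembly=assembly,
                        calls=calls, skipped=skipped)


def parse_region_string(text: str) -> tuple[GenomicInterval, CnvType]:
    """Parse 'chr11:100-200-DEL' (1-based inclusive) into internal coordinates."""
    m = _REGION_RE.match(text)
    if not m:
        raise ValueError(
            f"cannot parse region {text!r}; expected chrN:start-end-DEL|DUP")
    chrom, start, end, token = m.groups()
    start_1 = int(start.replace(",", ""))
    end_1 = int(end.replace(",", ""))
    if start_1 < 1 or start_1 > end_1:
        raise ValueError(f"bad coordinates in region {text!r}")
    return GenomicInterval(chrom, start_1 - 1, end_1), CnvType.parse(token)


# ---------------------------------------------------------------------------
# writing

def _vcf_header_text(records: CnvRecordSet, metric_names, prefix: str) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=cnvcurate",
             '##INFO=<ID=SVTYPE,Number=1,Type=String,'
             'Description="Type of structural variant">',
             '##INFO=<ID=END,Number=1,Type=Integer,'
             'Description="End position of the variant">',
             '##INFO=<ID=SVLEN,Number=1,Type=Integer,'
             'Description="Length of the variant">']
    for name in metric_names:
        lines.append(f'##INFO=<ID={name},Number=1,Type=Float,'
                     f'Description="Caller metric {name}">')
    lines += ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
              '##FORMAT=<ID=FT,Number=1,Type=String,'
              'Description="Genotype filter">',
              '##FILTER=<ID=LowQual,Description="Low quality">',
              '##FILTER=<ID=NO_ASSEMBLY,Description="No assembly support">']
    for chrom in sorted({c.interval.chrom for c in records.calls}):
        lines.append(f"##contig=<ID={prefix}{chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + records.sample)
    return "\n".join(lines) + "\n"


def write_calls(records: CnvRecordSet, path, fmt: str = "VCF",
                chr_prefix: bool = False) -> None:
    """Write a call set as VCF, BED or TSV.

    The writer is the inverse of the reader: reading a written file with an
    identity profile over the same metric names reproduces intervals, types
    and metrics exactly. Output is sorted, so write/read/write is
    byte-idempotent.
    """
    fmt = fmt.upper()
    records.sort()
    prefix = "chr" if chr_prefix else ""
    if fmt == "VCF":
        # The symbolic-allele dialect of the callers modeled here is VCF 4.2:
        # POS = first affected base (1-based), INFO END = last affected base,
        # |SVLEN| = END - POS + 1. htslib >= 1.21 rewrites END from SVLEN
        # under VCF 4.4 anchor-base semantics on output, so the writer emits
        # the 4.2 dialect as text; reading stays on pysam, whose in-memory
        # coordinates are unaffected.
        metric_names = sorted({k for c in records.calls for k in c.metrics})
        with open(path, "w") as out:
            out.write(_vcf_header_text(records, metric_names, prefix))
            for call in records.calls:
                svlen = call.length if call.type is CnvType.DUP else -call.length
                info = [f"SVTYPE={call.type.value}", f"END={call.interval.end}",
                        f"SVLEN={svlen}"]
                for name, value in sorted(call.metrics.items()):
                    info.append(f"{name}={value:g}")
                qual = "." if call.quality is None else f"{call.quality:g}"
                filt = ";".join(sorted(call.filter_status)) or "PASS"
                fmt_keys, fmt_vals = ["GT"], [call.genotype or "./."]
                if call.genotype_filter is not None:
                    fmt_keys.append("FT")
                    fmt_vals.append(call.genotype_filter)
                out.write("\t".join([
                    f"{prefix}{call.interval.chrom}",
                    str(call.interval.start + 1), ".", "N",
                    f"<{call.type.value}>", qual, filt, ";".join(info),
                    ":".join(fmt_keys), ":".join(fmt_vals)]) + "\n")
    elif fmt == "BED":
        with open(path, "w") as out:
            for call in records.calls:
                out.write(f"{prefix}{call.interval.chrom}\t{call.interval.start}\t"
                          f"{call.interval.end}\t{call.type.value}\n")
    elif fmt == "TSV":
        with open(path, "w") as out:
            out.write("chrom\tstart\tend\ttype\tcaller\tquality\tgenotype\tmetrics\n")
            for call in records.calls:
                metrics = ";".join(f"{k}={v:g}" for k, v in sorted(call.metrics.items()))
                qual = "" if call.quality is None else f"{call.quality:g}"
                out.write(f"{prefix}{call.interval.chrom}\t{call.interval.start}\t"
                          f"{call.interval.end}\t{call.type.value}\t{call.caller}\t"
                          f"{qual}\t{call.genotype or ''}\t{metrics}\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}; use VCF, BED or TSV")


def read_bed_intervals(path) -> list[GenomicInterval]:
    """Plain BED3 → interval list (for blacklist / gap tracks)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out
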