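"""Local annotation tables and the queries the ACMG engine runs on them.

A *resource bundle* is a directory of plain TSV tables distilled (by
external ETL, out of scope here) from the live databases a clinical CNV
pipeline consults — gene models with one representative transcript each
(MANE when available, else longest), ClinGen dosage-sensitivity curations,
gnomAD-style constraint metrics, ClinVar-style curated variants, and
population CNV frequencies from gnomAD/DGV/DECIPHER:

* ``genes.tsv``             gene models, family ids, disease association,
                            pLI / o-e upper bound / HI index, ClinGen
                            HI and TS scores
* ``dosage_regions.tsv``    curated HI / TS / benign-loss / benign-gain
                            genomic regions
* ``curated_variants.tsv``  null variants and last-exon pathogenic variants
* ``population_cnvs.tsv``   population CNVs with allele frequencies

Every table starts with a schema version line (``#cnvcurate-bundle-v1``).
Missing metrics are explicit nulls (empty field / ``NA``), never silent
zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from cnvcurate.intervals import CnvType, GenomicInterval
from cnvcurate.region_filters import reciprocal_overlap

SCHEMA_VERSION = "cnvcurate-bundle-v1"

# ClinGen dosage scores: 3 = sufficient evidence, 2 = some, 1 = little,
# 0 = none, 30 = autosomal recessive, 40 = dosage sensitivity unlikely.
ESTABLISHED_DOSAGE_SCORE = 3

GENE_COLUMNS = ["symbol", "chrom", "start", "end", "strand", "exon_starts",
                "exon_ends", "cds_start", "cds_end", "mane", "family",
                "disease_assoc", "pLI", "oe_upper", "hi_index",
                "clingen_hi", "clingen_ts"]
DOSAGE_COLUMNS = ["chrom", "start", "end", "kind", "label"]
VARIANT_COLUMNS = ["gene", "position", "consequence", "pathogenicity",
                   "in_last_exon"]
POPULATION_COLUMNS = ["chrom", "start", "end", "type", "af", "source"]

DOSAGE_KINDS = ("HI_region", "TS_region", "benign_loss_region",
                "benign_gain_region")


@dataclass(frozen=True)
class ExonModel:
    """Exon/CDS structure of one representative transcript.

    ``exons`` are genomic intervals in ascending genomic order; transcript
    order is this list for ``+`` strand genes and its reverse for ``-``.
    ``cds_start``/``cds_end`` bound the coding sequence in genomic
    coordinates (0-based half-open).
    """

    exons: tuple
    strand: str
    cds_start: int
    cds_end: int
    mane: bool

    def exons_transcript_order(self) -> tuple:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def last_exon(self) -> GenomicInterval:
        """Final exon in transcript (5'→3') direction."""
        return self.exons_transcript_order()[-1]

    def coding_intervals(self) -> list:
        """Per-exon CDS pieces in genomic order."""
        out = []
        for exon in self.exons:
            lo = max(exon.start, self.cds_start)
            hi = min(exon.end, self.cds_end)
            if hi > lo:
                out.append(GenomicInterval(exon.chrom, lo, hi))
        return out

    @property
    def coding_length(self) -> int:
        return sum(iv.length for iv in self.coding_intervals())

    def coding_offset(self, genomic_pos: int) -> int | None:
        """Translation-direction offset (0-based) of a coding genomic base."""
        pieces = self.coding_intervals()
        if self.strand == "-":
            pieces = list(reversed(pieces))
        offset = 0
        for piece in pieces:
            if piece.start <= genomic_pos < piece.end:
                if self.strand == "+":
                    return offset + (genomic_pos - piece.start)
                return offset + (piece.end - 1 - genomic_pos)
            offset += piece.length
        return None

    def deleted_coding_offsets(self, interval: GenomicInterval):
        """(bases removed, min coding offset removed) for a deletion."""
        removed = 0
        min_offset = None
        for piece in self.coding_intervals():
            o = piece.overlap_length(interval)
            if o == 0:
                continue
            removed += o
            lo = max(piece.start, interval.start)
            hi = min(piece.end, interval.end)
            # most 5' removed base in transcript direction
            pos = lo if self.strand == "+" else hi - 1
            off = self.coding_offset(pos)
            if off is not None and (min_offset is None or off < min_offset):
                min_offset = off
        return removed, min_offset

    def nmd_boundary_offset(self) -> int:
        """Coding offset of the NMD boundary: last junction minus 50 nt.

        Termination codons upstream of this offset are predicted to trigger
        nonsense-mediated decay.
        """
        exons_tx = self.exons_transcript_order()
        if len(exons_tx) < 2:
            return 0
        coding_before_last = 0
        for exon in exons_tx[:-1]:
            lo = max(exon.start, self.cds_start)
            hi = min(exon.end, self.cds_end)
            if hi > lo:
                coding_before_last += hi - lo
        return max(0, coding_before_last - 50)


@dataclass(frozen=True)
class GeneRecord:
    symbol: str
    interval: GenomicInterval
    exon_model: ExonModel
    family: str | None
    disease_associated: bool
    pli: float | None
    oe_upper: float | None
    hi_index: float | None
    clingen_hi: int | None
    clingen_ts: int | None

    @property
    def established_hi(self) -> bool:
        return self.clingen_hi == ESTABLISHED_DOSAGE_SCORE

    @property
    def established_ts(self) -> bool:
        return self.clingen_ts == ESTABLISHED_DOSAGE_SCORE


@dataclass(frozen=True)
class DosageRegion:
    interval: GenomicInterval
    kind: str
    label: str


@dataclass(frozen=True)
class CuratedVariant:
    gene: str
    position: int
    consequence: str  # nonsense | frameshift | splicing | other
    pathogenicity: str
    in_last_exon: bool

    @property
    def is_null(self) -> bool:
        return self.consequence in ("nonsense", "frameshift", "splicing")

    @property
    def is_pathogenic(self) -> bool:
        return self.pathogenicity.lower() in ("pathogenic", "likely_pathogenic")


@dataclass(frozen=True)
class PopulationCnv:
    interval: GenomicInterval
    type: CnvType
    af: float
    source: str


class ResourceLoadError(ValueError):
    pass


def _read_table(path: Path, required_columns) -> pd.DataFrame:
    if not path.exists():
        raise ResourceLoadError(f"missing resource table: {path.name}")
    with open(path) as fh:
        first = fh.readline().strip()
    if first.lstrip("#") != SCHEMA_VERSION:
        raise ResourceLoadError(
            f"{path.name}: first line must be #{SCHEMA_VERSION}, got {first!r}")
    df = pd.read_csv(path, sep="\t", skiprows=1, dtype=str, keep_default_na=False)
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise ResourceLoadError(f"{path.name}: missing columns {', '.join(missing)}")
    return df


def _opt_float(token: str) -> float | None:
    token = token.strip()
    if token in ("", "NA", "."):
        return None
    return float(token)


def _opt_int(token: str) -> int | None:
    value = _opt_float(token)
    return None if value is None else int(value)


def _bool(token: str) -> bool:
    return token.strip().lower() in ("1", "true", "yes", "y")


def predicted_hi(gene: GeneRecord) -> bool:
    """Predicted-haploinsufficient: pLI >= 0.9 AND o/e upper < 0.35 AND HI index <= 10.

    Any missing metric makes the prediction false — absence of evidence is
    not treated as evidence of intolerance.
    """
    if gene.pli is None or gene.oe_upper is None or gene.hi_index is None:
        return False
    return gene.pli >= 0.9 and gene.oe_upper < 0.35 and gene.hi_index <= 10


@dataclass
class ResourceBundle:
    """Loaded and indexed annotation tables."""

    genes: dict  # symbol -> GeneRecord
    dosage_regions: list
    curated_variants: list
    population_cnvs: list
    _gene_trees: dict = field(default_factory=dict, repr=False)
    _dosage_trees: dict = field(default_factory=dict, repr=False)
    _pop_trees: dict = field(default_factory=dict, repr=False)
    _variants_by_gene: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for gene in self.genes.values():
            self._gene_trees.setdefault(gene.interval.chrom, IntervalTree()).addi(
                gene.interval.start, gene.interval.end, gene)
        for region in self.dosage_regions:
            self._dosage_trees.setdefault(region.interval.chrom, IntervalTree()).addi(
                region.interval.start, region.interval.end, region)
        for pop in self.population_cnvs:
            self._pop_trees.setdefault(pop.interval.chrom, IntervalTree()).addi(
                pop.interval.start, pop.interval.end, pop)
        for var in self.curated_variants:
            self._variants_by_gene.setdefault(var.gene, []).append(var)

    # -- queries ------------------------------------------------------------

    def overlapping_genes(self, interval: GenomicInterval) -> list:
        """Genes intersecting the interval, each with an overlap kind.

        ``complete``: the whole gene lies within the CNV. ``internal``: the
        CNV lies within the gene. Partial overlaps are sided on genomic
        coordinates, then mapped through strand so the labels name the
        transcript end disrupted (``partial_5prime`` / ``partial_3prime``).
        """
        tree = self._gene_trees.get(interval.chrom)
        if tree is None:
            return []
        hits = []
        for node in tree.overlap(interval.start, interval.end):
            gene = node.data
            if interval.contains(gene.interval):
                kind = "complete"
            elif gene.interval.contains(interval):
                kind = "internal"
            else:
                left = interval.start <= gene.interval.start  # CNV covers gene's left end
                if gene.exon_model.strand == "+":
                    kind = "partial_5prime" if left else "partial_3prime"
                else:
                    kind = "partial_3prime" if left else "partial_5prime"
            hits.append((gene, kind))
        hits.sort(key=lambda h: (h[0].interval.start, h[0].symbol))
        return hits

    def count_genes(self, interval: GenomicInterval) -> int:
        """Overlapping gene count with gene-family collapsing.

        A family with two or more members inside the CNV, none of them
        disease-associated, contributes a single unit — counting paralogs
        individually would inflate the gene-number evidence.
        """
        genes = [g for g, _ in self.overlapping_genes(interval)]
        families: dict = {}
        singles = 0
        for gene in genes:
            if gene.family:
                families.setdefault(gene.family, []).append(gene)
            else:
                singles += 1
        count = singles
        for members in families.values():
            if len(members) >= 2 and not any(m.disease_associated for m in members):
                count += 1
            else:
                count += len(members)
        return count

    def dosage_hits(self, interval: GenomicInterval, cnv_type: CnvType) -> list:
        """Dosage-sensitive elements relevant to the CNV type.

        DEL queries ClinGen HI(3) genes, HI regions and benign-loss
        regions; DUP the TS / benign-gain analogues. Each hit carries the
        fraction of the established element covered by the CNV.
        """
        hits = []
        if cnv_type is CnvType.DEL:
            region_kinds = ("HI_region", "benign_loss_region")
        else:
            region_kinds = ("TS_region", "benign_gain_region")
        tree = self._dosage_trees.get(interval.chrom)
        if tree is not None:
            for node in sorted(tree.overlap(interval.start, interval.end),
                               key=lambda n: (n.begin, n.end)):
                region = node.data
                if region.kind in region_kinds:
                    frac = interval.overlap_length(region.interval) / region.interval.length
                    hits.append((region, frac))
        for gene, _ in self.overlapping_genes(interval):
            established = (gene.established_hi if cnv_type is CnvType.DEL
                           else gene.established_ts)
            if established:
                frac = interval.overlap_length(gene.interval) / gene.interval.length
                hits.append((gene, frac))
        return hits

    def variants_in_gene(self, symbol: str) -> list:
        return list(self._variants_by_gene.get(symbol, []))

    def max_population_frequency(self, interval: GenomicInterval,
                                 cnv_type: CnvType,
                                 ro_threshold: float = 0.70):
        """Max allele frequency over matching population CNVs, with source.

        A population CNV matches when it has the same type and at least
        ``ro_threshold`` reciprocal overlap with the query. Returns
        ``(None, None)`` when nothing matches.
        """
        tree = self._pop_trees.get(interval.chrom)
        best_af, best_source = None, None
        if tree is not None:
            for node in tree.overlap(interval.start, interval.end):
                pop = node.data
                if pop.type is not cnv_type:
                    continue
                if reciprocal_overlap(interval, pop.interval) >= ro_threshold:
                    if best_af is None or pop.af > best_af:
                        best_af, best_source = pop.af, pop.source
        return best_af, best_source


def load_resources(bundle_dir) -> ResourceBundle:
    """Load and validate a resource bundle directory."""
    bundle_dir = Path(bundle_dir)
    genes_df = _read_table(bundle_dir / "genes.tsv", GENE_COLUMNS)
    dosage_df = _read_table(bundle_dir / "dosage_regions.tsv", DOSAGE_COLUMNS)
    variants_df = _read_table(bundle_dir / "curated_variants.tsv", VARIANT_COLUMNS)
    pop_df = _read_table(bundle_dir / "population_cnvs.tsv", POPULATION_COLUMNS)

    genes: dict = {}
    for i, row in genes_df.iterrows():
        try:
            chrom = row["chrom"]
            exon_starts = [int(x) for x in row["exon_starts"].split(",") if x]
            exon_ends = [int(x) for x in row["exon_ends"].split(",") if x]
            if len(exon_starts) != len(exon_ends) or not exon_starts:
                raise ValueError("exon_starts/exon_ends mismatch")
            exons = tuple(GenomicInterval(chrom, s, e)
                          for s, e in zip(exon_starts, exon_ends))
            for a, b in zip(exons, exons[1:]):
                if a.end > b.start:
                    raise ValueError("exons overlap or are unsorted")
            strand = row["strand"]
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")
            gene = GeneRecord(
                symbol=row["symbol"],
                interval=GenomicInterval(chrom, int(row["start"]), int(row["end"])),
                exon_model=ExonModel(exons=exons, strand=strand,
                                     cds_start=int(row["cds_start"]),
                                     cds_end=int(row["cds_end"]),
                                     mane=_bool(row["mane"])),
                family=row["family"].strip() or None,
                disease_associated=_bool(row["disease_assoc"]),
                pli=_opt_float(row["pLI"]),
                oe_upper=_opt_float(row["oe_upper"]),
                hi_index=_opt_float(row["hi_index"]),
                clingen_hi=_opt_int(row["clingen_hi"]),
                clingen_ts=_opt_int(row["clingen_ts"]),
            )
        except (ValueError, KeyError) as exc:
            raise ResourceLoadError(f"genes.tsv row {i + 3}: {exc}") from exc
        if gene.symbol in genes:
            raise ResourceLoadError(f"genes.tsv: duplicate symbol {gene.symbol}")
        genes[gene.symbol] = gene

    dosage = []
    for i, row in dosage_df.iterrows():
        if row["kind"] not in DOSAGE_KINDS:
            raise ResourceLoadError(
                f"dosage_regions.tsv row {i + 3}: unknown kind {row['kind']!r}")
        dosage.append(DosageRegion(
            interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            kind=row["kind"], label=row["label"]))

    variants = []
    for i, row in variants_df.iterrows():
        var = CuratedVariant(gene=row["gene"], position=int(row["position"]),
                             consequence=row["consequence"],
                             pathogenicity=row["pathogenicity"],
                             in_last_exon=_bool(row["in_last_exon"]))
        gene = genes.get(var.gene)
        if gene is not None and not (
                gene.interval.start <= var.position < gene.interval.end):
            raise ResourceLoadError(
                f"curated_variants.tsv row {i + 3}: position {var.position} "
                f"outside gene {var.gene} span")
        variants.append(var)

    population = []
    for i, row in pop_df.iterrows():
        af = float(row["af"])
        if not 0 <= af <= 1 or math.isnan(af):
            raise ResourceLoadError(
                f"population_cnvs.tsv row {i + 3}: allele frequency {af} out of [0,1]")
        population.append(PopulationCnv(
            interval=GenomicInterval(row["chrom"], int(row["start"]), int(row["end"])),
            type=CnvType.parse(row["type"]), af=af, source=row["source"]))

    return ResourceBundle(genes=genes, dosage_regions=dosage,
                          curated_variants=variants, population_cnvs=population)
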