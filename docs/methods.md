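# Methods

This note documents the models, rules and design choices behind
`cnvcurate`, in the order the pipeline applies them.

## Scope and coordinate model

The package covers the *post-calling* half of a germline CNV workflow: it
consumes per-caller DEL/DUP call sets (VCF with symbolic alleles, or BED)
and produces filtered, merged, region-cleaned and ACMG/ClinGen-classified
CNVs. Running the callers themselves, read alignment, and liftover are out
of scope; caller outputs are modeled as inputs.

Internally every interval is 0-based half-open (`[start, end)`), and
chromosome names carry no `chr` prefix. VCF input is converted at the
boundary: a symbolic-allele record with POS=1001 and INFO END=2000 becomes
`[1000, 2000)`. Records carrying SVLEN but no END are completed as
END = POS + |SVLEN|. User-typed region strings (`chr11:100-200-DEL`) are
read as 1-based inclusive, the genome-browser convention. Only symbolic
`<DEL>`/`<DUP>` records are interpreted; breakends, inversions and
insertions are skipped and counted. The minimum CNV size is 50 bp.

A note on VCF output: htslib ≥ 1.21 applies VCF 4.4 semantics on write and
recomputes INFO END from SVLEN with anchor-base arithmetic, which is
incompatible with the 4.2 dialect (END = last affected base) used by the
short-read callers modeled here. The writer therefore emits VCF text in the
4.2 dialect directly; reading uses pysam throughout. VCF `Type=Float`
fields are stored in 32 bits by htslib, so metric values read back are
snapped to six significant digits to recover the printed decimal exactly —
otherwise a printed `0.05` would reload as `0.05000000074` and flip
strict-inequality filter boundaries.

## Caller-specific confidence filters

Each rule is a pure predicate over one call; all inequalities are strict,
exactly as stated, so values equal to a threshold stay on the keep side:

| caller | removed when |
|---|---|
| CNVpytor | `pytorP1` > 0.05, or `Q0` > 0.9, or 0.75 < `pytorRD` < 1.25 |
| ControlFREEC | `W` > 0.05 or `KS` > 0.05 |
| delly, Manta | site FILTER or per-sample FT not PASS, or GT = 0/0 |
| lumpy | QUAL < 120 |
| Wham | `max_CW` < 0.2, or DEL with `TF` < 3, or DUP with `U` < 2 |
| GRIDSS | FILTER contains NO_ASSEMBLY |
| ExomeDepth | `BF` < 15, or DEL ratio > 0.8, or DUP ratio < 1.1 |
| GATK4 gCNV | QS below min(1000, max(400, 10·nt)) for CN=0 DEL; min(1000, max(100, 10·nt)) for CN=1 DEL; min(400, max(50, 4·nt)) for DUP |

Design choices:

* The CNVpytor conditions are combined **disjunctively**, with the two
  `pytorRD` bounds read as one band (read depth near diploid → likely
  artifact). A conjunctive combination would almost never fire; the band
  reading matches the metric's meaning. `conjunctive=True` switches the
  behavior for users who prefer the other reading.
* The NO_ASSEMBLY rule is applied to GRIDSS only; Manta is covered by the
  PASS/genotype rule.
* GATK4 DELs with copy-number state outside {0, 1} fall outside the QS
  rule's domain and are kept with a warning.
* Missing metrics follow a policy switch: `lenient` (default) keeps the
  call and logs a warning — caller output dialects drift across versions
  and a missing key should not silently drop data — while `strict` raises.
* Callers with no stated rule (cn.mops, xhmm, ECOLE, and the long-read
  callers cuteSV, SVision-pro, Sniffles, NanoVar, DeBreak) pass through
  unfiltered.

## Ensemble merging

Calls are partitioned by (chromosome, type, size bin) and clustered within
each partition. Size bins tile [50 bp, ∞) half-open, so a boundary length
(exactly 500 bp) maps to exactly one bin, the upper one:

* WGS / long-read: SS [50, 500), S [500, 5 000), M [5 000, 100 000),
  L [100 000, ∞)
* WES: S [50, 10 000), M [10 000, 100 000), L [100 000, ∞)

Two calls are breakpoint-compatible when both |Δstart| and |Δend| are
within `max_dist`. The shipped default 0.5 is interpreted as a **fraction
of the larger variant's length** — an absolute 0.5 bp bound would be
degenerate — while values ≥ 1 are taken as absolute base pairs, so both
semantics of the SURVIVOR-style parameter are available.

Clustering is greedy single linkage with deterministic seeding (calls
sorted by start, end, type, caller): the cluster grows by adding, per
caller not yet represented, the compatible pool call closest to the seed
(L1 breakpoint distance). A caller contributes at most one call per
cluster; surplus calls stay in the pool and seed their own clusters. When
no caller occurs twice in a compatibility component — the normal case —
this reduces exactly to the connected components of the compatibility
relation, which is what the brute-force oracle computes.

Each cluster's representative interval takes the per-endpoint median of
its supporting calls, rounded down (an average over callers, rather than
trusting any single "best" caller). Consensus selection keeps a cluster
when at least `min_support` of its callers belong to the tool set
configured for its (type, bin) cell. Optimal per-cell tool sets are
cohort-dependent tuning; the shipped default admits all registered callers
and requires two concordant callers in the noisy small bins (SS, S) and
one in M/L, and the whole table is editable YAML.

## Region filtering

Reciprocal overlap of intervals a and b is min(o/|a|, o/|b|); a consensus
CNV is removed when its RO with **any single** blacklist or gap region is
≥ 0.70. Per-region (not union) semantics follow from the per-region
phrasing of the rule; a CNV tiled by many small regions none reaching the
cut-off is kept, and `mode="union"` is available for the other behavior.
The threshold is inclusive (≥) and configurable. Blacklist/gap filtering
applies to short-read platform classes only (HD-WGS, LD-WGS, WES);
long-read calls are not subject to it.

## Annotation resources

The engine queries a directory of plain TSV tables distilled from the live
clinical databases (HGNC/ENSEMBL gene models with MANE-preferred — else
longest — transcripts, OMIM-derived disease association, ClinGen dosage
curations, gnomAD constraint, ClinVar curated variants, gnomAD/DGV/DECIPHER
population CNVs). The ETL from those databases is deliberately out of
scope; the repository ships a synthetic toy bundle and the schema. Missing
metrics are explicit nulls, never silent zeros. Every table starts with a
schema version line.

Key queries:

* **Gene overlap kinds** — complete (gene ⊆ CNV), internal (CNV ⊆ gene),
  or partial; partial sides are determined on genomic coordinates and then
  mapped through strand to 5'/3' labels.
* **Gene counting with family collapsing** — a gene family with ≥2 members
  inside the CNV, none disease-associated, counts as a single unit, so
  paralog clusters do not inflate the gene-number evidence.
* **Predicted haploinsufficiency** — pLI ≥ 0.9 AND o/e upper bound < 0.35
  AND HI index ≤ 10, with the inclusive/exclusive directions exactly as
  stated; any missing metric makes the prediction false.
* **Population frequency** — the maximum allele frequency over population
  CNVs of the same type with ≥ 70% reciprocal overlap (the matching rule
  is configurable; 70% RO with type identity is the package's choice).

## ACMG/ClinGen scoring

The rubric (criterion ids, default/min/max points, gene-count bands,
classification bands) is shipped as editable YAML — data, not code.
Automatic scoring covers Sections 1–3 and the population-frequency
criterion of Section 4; clinical case, segregation and de-novo criteria
enter through `merge_user_evidence`, where a user item overrides the
engine's item for the same criterion and out-of-range points are rejected.

Loss arm (priority order; the highest-priority applicable criterion is
scored): 2A complete overlap of an established HI gene/region (+1.00);
partial or intragenic overlap of an HI gene routed through the PVS1 tree
(2C/2D/2E, points 0.90/0.45/0.30/0.15/0 for very-strong/strong/moderate/
supporting/none); 2B partial HI-region overlap (0); 2F containment in a
benign-loss region with no additional genes (−1.00); 2G benign overlap
with additional genes (0); 2H at least one predicted-HI gene (+0.15).
Gain arm mirrors it over triplosensitive and benign-gain elements; partial
or intragenic duplications take conservative 0-point defaults because
tandem-versus-inserted orientation is unknowable from a depth-based call.

PVS1 tree for deletions: (i) no coding base removed → none; (ii) frame:
removed coding bases mod 3; (iii) frameshift with the most 5' removed base
upstream of the NMD boundary (coding position of the last exon–exon
junction minus 50 nt) → very strong when loss of function is an
established disease mechanism (disease-associated gene with curated null
variants), stepped down to moderate otherwise; (iv) NMD-escaping or
in-frame events → strong when a curated pathogenic variant lies in or
downstream of the removed region (last-exon pathogenic variants included)
or when > 10% of the protein is removed, else moderate. Finer sub-branches
(exon skipping predictions, alternative-transcript rescue) are not
modeled.

Gene-count bands: loss 25–34 genes → +0.45, ≥35 → +0.90; gain 35–49 →
+0.45, ≥50 → +0.90. Population frequency ≥ 1% (configurable) contributes
−1.00. Classification bands: ≥ 0.99 Pathogenic; 0.90–0.98 Likely
pathogenic; −0.89–0.89 VUS; −0.98 to −0.90 Likely benign; ≤ −0.99 Benign.
Band edges are tested at ±0.89/0.90/0.98/0.99.

## Synthetic fixtures and what the tests show

The fixture module fabricates every input: per-caller VCFs with records
at, below and above each filter threshold; an annotation bundle with a
five-exon HI gene engineered so single-exon deletions exercise every PVS1
branch, gene families with and without a disease-associated member, eight
constraint-corner genes around the predicted-HI cut-offs, dosage regions
of all four kinds, and population CNVs at AF 0.0001/0.001/0.02/0.05; 100
randomized merge scenarios; and random CNV-versus-blacklist sets. Expected
outcomes are computed at generation time by naive reference
implementations (literal rule transcription, union-find transitive
closure, all-pairs quadratic scans) that share no code with the production
modules, and regeneration with the same seed is byte-identical.

Merge scenarios place planted events ≥ 2 Mb apart — beyond any reachable
breakpoint-distance bound for the simulated 60 bp–500 kb events — so a
caller never contributes two calls to one compatibility component and the
greedy clustering is provably identical to the closure oracle on these
instances. The toy genome (two to eight 10 Mb chromosomes) keeps the whole
suite and the acceptance script in the low seconds.

What passing does **not** show: the fixtures do not emulate real caller
error profiles, breakpoint-resolution biases, segmental-duplication
artifacts, or the content of the live clinical databases. Agreement here
demonstrates that the arithmetic and rule logic are implemented exactly,
not that the thresholds are optimal for any particular cohort.

## Known limitations

* Only the first sample of a multi-sample VCF is read.
* The gain-side PVS1 analogue is intentionally shallow (conservative
  0-point defaults) pending orientation-aware duplication assessment.
* DECIPHER-style frequencies are modeled as a single AF column; resources
  without a well-defined AF must be reduced to one during ETL.
* Section 5 (inheritance) is user-supplied only; the engine never infers
  de novo status.
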