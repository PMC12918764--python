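# cnvcurate

Post-calling curation and clinical interpretation of germline copy-number
variants (CNVs). `cnvcurate` takes the raw DEL/DUP call sets that individual
CNV callers emit and turns them into a classified, evidence-annotated report:

1. **Caller-specific confidence filtering** — each caller (CNVpytor,
   ControlFREEC, delly, Manta, lumpy, Wham, GRIDSS, ExomeDepth, GATK4 gCNV)
   ships its own quality metrics; each gets its own exclusion rule (e.g.
   CNVpytor calls with e-value `pytorP1` > 0.05, zero-mapping-quality fraction
   `Q0` > 0.9, or a near-diploid read-depth ratio 0.75 < `pytorRD` < 1.25 are
   removed; GATK4 calls are removed when their quality score falls below a
   piecewise threshold in the number of exons spanned,
   `min(1000, max(400, 10·nt))` for CN=0 deletions).
2. **Size- and type-aware ensemble merging** — surviving calls are binned by
   type (DEL/DUP) and size (SS/S/M/L; 50–500 bp, 500 bp–5 kb, 5–100 kb,
   >100 kb for WGS and long reads; S/M/L with S = 50 bp–10 kb for WES) and
   clustered by single linkage under a SURVIVOR-style breakpoint-proximity
   bound (default: 0.5 × the larger variant's length per endpoint). Each
   cluster becomes one consensus CNV; a configurable per-(type, bin) tool set
   and minimum support decide which clusters survive.
3. **Region filtering** — consensus CNVs with ≥70% reciprocal overlap
   (RO(a,b) = min(o/|a|, o/|b|)) with a mappability-blacklist or assembly-gap
   region are removed (short-read platforms only).
4. **Semiquantitative ACMG/ClinGen interpretation** — each CNV is scored
   against local annotation tables (gene models, ClinGen
   haploinsufficiency/triplosensitivity curations, gnomAD-style constraint,
   ClinVar-style curated variants, population CNV frequencies). Evidence
   points are summed and banded:
   total ≥ 0.99 → Pathogenic, 0.90–0.98 → Likely pathogenic,
   −0.89–0.89 → VUS, −0.98 – −0.90 → Likely benign, ≤ −0.99 → Benign.
   Intragenic deletions are graded through a PVS1-style loss-of-function
   decision tree (coding loss → reading frame → nonsense-mediated-decay
   prediction via the last-junction-minus-50-nt rule → protein fraction
   removed and curated-variant context). Clinical evidence the engine cannot
   derive (de novo status, segregation) is merged in as user-supplied items.

The package is aimed at bioinformaticians building clinical CNV pipelines
and at method developers who need a transparent, fully testable reference
for the semiquantitative scoring arithmetic.

## Worked example

All inputs below are generated by the package's own synthetic-fixture module
(`cnvcurate fixtures`), so the example runs anywhere:

```bash
cnvcurate fixtures --seed 1 --out fx
cnvcurate interpret --resources fx/bundle \
    --region "chr1:995001-1055000-DEL" \
    --region "1:7550001-7600000-DUP"
```

prints

```
1:995001-1055000 DEL: Pathogenic (total +1)
1:7550001-7600000 DUP: Benign (total -2)
```

The first CNV deletes the whole of a ClinGen-curated haploinsufficient gene:
criterion 2A contributes +1.00, which alone reaches the Pathogenic band. The
second duplication lies inside a curated benign-gain region (−1.00) and
matches a population CNV at 5% allele frequency (−1.00), landing at −2.00,
well inside the Benign band. A full pipeline run
(`cnvcurate run --config run.yaml`) writes a per-evidence report:

```
cnv               type  criterion  points  rationale                                               provenance
1:995001-1055000  DEL   L1A        0       overlaps 3 protein-coding gene(s)                       auto
1:995001-1055000  DEL   L2A        1       complete overlap of established HI element(s): HIGENE1  auto
1:995001-1055000  DEL   L3A        0       3 protein-coding genes (collapsed)                      auto
1:995001-1055000  DEL   TOTAL      1       Pathogenic                                              summary
```

plus a `manifest.json` with input digests and per-stage record counts.

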