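# Semiquantitative CNV classification rubric (ClinGen/ACMG technical-standard
# point scheme). This is data, not code: point updates do not require a
# package release. Criterion ids are prefixed L (copy-number loss) or G
# (copy-number gain); Section 5 ids are shared between the two arms.
version: 1
classification_bands:
  # total >= 0.99 -> Pathogenic; 0.90..0.98 -> Likely pathogenic;
  # -0.89..0.89 -> VUS; -0.98..-0.90 -> Likely benign; <= -0.99 -> Benign
  pathogenic_min: 0.99
  likely_pathogenic_min: 0.90
  likely_benign_max: -0.90
  benign_max: -0.99
gene_count_bands:
  loss: {tier1_min: 25, tier1_points: 0.45, tier2_min: 35, tier2_points: 0.90}
  gain: {tier1_min: 35, tier1_points: 0.45, tier2_min: 50, tier2_points: 0.90}
pvs1_points: {very_strong: 0.90, strong: 0.45, moderate: 0.30, supporting: 0.15, none: 0.0}
common_af_threshold: 0.01
criteria:
  # ---- loss, section 1
  L1A: {section: 1, applicability: loss, default: 0.0, min: 0.0, max: 0.0,
        description: "Contains protein-coding genes or other known functionally important elements"}
  L1B: {section: 1, applicability: loss, default: 0.0, min: -0.6, max: 0.0,
        description: "Does not contain protein-coding genes or known functionally important elements"}
  # ---- loss, section 2
  L2A: {section: 2, applicability: loss, default: 1.0, min: 0.0, max: 1.0,
        description: "Complete overlap of an established haploinsufficient gene or genomic region"}
  L2B: {section: 2, applicability: loss, default: 0.0, min: 0.0, max: 0.0,
        description: "Partial overlap of an established haploinsufficient genomic region"}
  L2C: {section: 2, applicability: loss, default: 0.0, min: 0.0, max: 0.9,
        description: "Partial overlap of the 5' end of an established haploinsufficient gene"}
  L2D: {section: 2, applicability: loss, default: 0.0, min: 0.0, max: 0.9,
        description: "Partial overlap of the 3' end of an established haploinsufficient gene"}
  L2E: {section: 2, applicability: loss, default: 0.0, min: 0.0, max: 0.9,
        description: "Both breakpoints within the same haploinsufficient gene; points per PVS1 strength"}
  L2F: {section: 2, applicability: loss, default: -1.0, min: -1.0, max: -1.0,
        description: "Completely contained within an established benign copy-number-loss region"}
  L2G: {section: 2, applicability: loss, default: 0.0, min: 0.0, max: 0.0,
        description: "Overlaps an established benign loss region but includes additional protein-coding genes"}
  L2H: {section: 2, applicability: loss, default: 0.15, min: 0.0, max: 0.15,
        description: "Involves at least one gene predicted haploinsufficient from constraint metrics"}
  # ---- loss, section 3 (gene count)
  L3A: {section: 3, applicability: loss, default: 0.0, min: 0.0, max: 0.0,
        description: "0-24 protein-coding genes"}
  L3B: {section: 3, applicability: loss, default: 0.45, min: 0.45, max: 0.45,
        description: "25-34 protein-coding genes"}
  L3C: {section: 3, applicability: loss, default: 0.9, min: 0.9, max: 0.9,
        description: "35 or more protein-coding genes"}
  # ---- loss, section 4
  L4A: {section: 4, applicability: loss, default: 0.3, min: 0.0, max: 0.45,
        description: "Reported proband with a consistent, specific phenotype (user-supplied)"}
  L4O: {section: 4, applicability: loss, default: -1.0, min: -1.0, max: 0.0,
        description: "Overlap with common population variation"}
  # ---- gain, section 1
  G1A: {section: 1, applicability: gain, default: 0.0, min: 0.0, max: 0.0,
        description: "Contains protein-coding genes or other known functionally important elements"}
  G1B: {section: 1, applicability: gain, default: 0.0, min: -0.6, max: 0.0,
        description: "Does not contain protein-coding genes or known functionally important elements"}
  # ---- gain, section 2
  G2A: {section: 2, applicability: gain, default: 1.0, min: 0.0, max: 1.0,
        description: "Complete overlap of an established triplosensitive gene or genomic region"}
  G2B: {section: 2, applicability: gain, default: 0.0, min: 0.0, max: 0.0,
        description: "Partial overlap of an established triplosensitive genomic region or gene"}
  G2C: {section: 2, applicability: gain, default: -1.0, min: -1.0, max: -1.0,
        description: "Completely contained within an established benign copy-number-gain region"}
  G2D: {section: 2, applicability: gain, default: 0.0, min: 0.0, max: 0.0,
        description: "Overlaps an established benign gain region but includes additional protein-coding genes"}
  G2I: {section: 2, applicability: gain, default: 0.0, min: 0.0, max: 0.9,
        description: "One or both breakpoints within a gene; insertion site/orientation unknown"}
  # ---- gain, section 3 (gene count)
  G3A: {section: 3, applicability: gain, default: 0.0, min: 0.0, max: 0.0,
        description: "0-34 protein-coding genes"}
  G3B: {section: 3, applicability: gain, default: 0.45, min: 0.45, max: 0.45,
        description: "35-49 protein-coding genes"}
  G3C: {section: 3, applicability: gain, default: 0.9, min: 0.9, max: 0.9,
        description: "50 or more protein-coding genes"}
  # ---- gain, section 4
  G4A: {section: 4, applicability: gain, default: 0.3, min: 0.0, max: 0.45,
        description: "Reported proband with a consistent, specific phenotype (user-supplied)"}
  G4O: {section: 4, applicability: gain, default: -1.0, min: -1.0, max: 0.0,
        description: "Overlap with common population variation"}
  # ---- section 5 (inheritance / de novo; user-supplied, both arms)
  5A: {section: 5, applicability: both, default: 0.45, min: 0.0, max: 0.45,
       description: "De novo occurrence (phenotype consistency per points)"}
  5B: {section: 5, applicability: both, default: 0.3, min: 0.0, max: 0.3,
       description: "Segregation among affected family members"}
  5C: {section: 5, applicability: both, default: 0.15, min: 0.0, max: 0.15,
       description: "Limited segregation or family history information"}
  5D: {section: 5, applicability: both, default: 0.0, min: -0.3, max: 0.45,
       description: "Inheritance pattern or phenotype evidence of uncertain direction"}
  5F: {section: 5, applicability: both, default: -0.45, min: -0.45, max: 0.0,
       description: "Inherited from an apparently unaffected parent"}
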