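{
  "description": "SYNTHETIC placeholder weight table. Per-allele betas (mmol/L per effect-allele copy) approximate published GLGC orientations and magnitudes for the 11-SNP LDL-c panel; replace with the exact consortium coefficients for any real analysis. ref_freq values are approximate 1000G European effect-allele frequencies used only as simulator defaults. rs7412 counts the epsilon2-defining T allele, hence its negative beta.",
  "snps": [
    {"rsid": "rs2479409", "gene": "PCSK9",        "effect_allele": "G", "other_allele": "A", "beta": 0.052,  "ref_freq": 0.34},
    {"rsid": "rs629301",  "gene": "CELSR2-SORT1", "effect_allele": "T", "other_allele": "G", "beta": 0.150,  "ref_freq": 0.78},
    {"rsid": "rs1367117", "gene": "APOB",         "effect_allele": "A", "other_allele": "G", "beta": 0.100,  "ref_freq": 0.33},
    {"rsid": "rs4299376", "gene": "ABCG8",        "effect_allele": "G", "other_allele": "T", "beta": 0.071,  "ref_freq": 0.31},
    {"rsid": "rs1564348", "gene": "SLC22A1",      "effect_allele": "C", "other_allele": "T", "beta": 0.014,  "ref_freq": 0.17},
    {"rsid": "rs1800562", "gene": "HFE",          "effect_allele": "G", "other_allele": "A", "beta": 0.057,  "ref_freq": 0.93},
    {"rsid": "rs3757354", "gene": "MYLIP",        "effect_allele": "C", "other_allele": "T", "beta": 0.037,  "ref_freq": 0.77},
    {"rsid": "rs8017377", "gene": "NYNRIN",       "effect_allele": "A", "other_allele": "G", "beta": 0.029,  "ref_freq": 0.47},
    {"rsid": "rs6511720", "gene": "LDLR",         "effect_allele": "G", "other_allele": "T", "beta": 0.180,  "ref_freq": 0.89},
    {"rsid": "rs429358",  "gene": "APOE",         "effect_allele": "C", "other_allele": "T", "beta": 0.120,  "ref_freq": 0.155},
    {"rsid": "rs7412",    "gene": "APOE",         "effect_allele": "T", "other_allele": "C", "beta": -0.400, "ref_freq": 0.063}
  ],
  "apoe_diplotype_weights": {
    "E2/E2": -0.90,
    "E2/E3": -0.38,
    "E2/E4": -0.20,
    "E3/E3": 0.00,
    "E3/E4": 0.10,
    "E4/E4": 0.22
  }
}
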