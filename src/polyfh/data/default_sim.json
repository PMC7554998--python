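{
  "description": "Default synthetic-cohort configuration. Group effect-allele frequencies are SYNTHETIC approximations: EUR columns mirror 1000G European frequencies; the FH mutation-negative column applies raising-allele enrichment on the associated SNPs at the odds-ratio scale reported for such cohorts; the mutation-positive column applies roughly 40% of that shift. DLCN component margins, LDL-c category bands, diagnostic-class proportions, age and sex follow the study-population marginal frequencies.",
  "n_per_group": {"EUR": 503, "FH_Mneg": 420, "FH_Mpos": 250},
  "mode": "frequency-shift",
  "freq_table": {
    "EUR":     {"rs2479409": 0.34, "rs629301": 0.78, "rs1367117": 0.33, "rs4299376": 0.31, "rs1564348": 0.17, "rs1800562": 0.93, "rs3757354": 0.77, "rs8017377": 0.47, "rs6511720": 0.89, "rs429358": 0.155, "rs7412": 0.063},
    "FH_Mneg": {"rs2479409": 0.41, "rs629301": 0.84, "rs1367117": 0.38, "rs4299376": 0.42, "rs1564348": 0.17, "rs1800562": 0.93, "rs3757354": 0.82, "rs8017377": 0.47, "rs6511720": 0.93, "rs429358": 0.165, "rs7412": 0.035},
    "FH_Mpos": {"rs2479409": 0.37, "rs629301": 0.80, "rs1367117": 0.35, "rs4299376": 0.35, "rs1564348": 0.17, "rs1800562": 0.93, "rs3757354": 0.79, "rs8017377": 0.47, "rs6511720": 0.91, "rs429358": 0.16,  "rs7412": 0.05}
  },
  "liability": {
    "residual_sd": 0.8,
    "selection_quantile": {"FH_Mneg": 0.05, "FH_Mpos": 0.5}
  },
  "monogenic_split": {"LDLR": 0.924, "APOB": 0.076},
  "dlcn_margins": {
    "FH_Mneg": {"1a": 0.435, "1b": 0.603, "2a": 0.051, "2b": 0.208, "3a": 0.096, "3b": 0.049, "4a": 0.137, "4b": 0.184},
    "FH_Mpos": {"1a": 0.396, "1b": 0.685, "2a": 0.094, "2b": 0.373, "3a": 0.089, "3b": 0.044, "4a": 0.182, "4b": 0.200}
  },
  "ldl_category_probs": {
    "FH_Mneg": {"1": 0.148, "2": 0.038, "3": 0.405, "4": 0.371, "5": 0.038},
    "FH_Mpos": {"1": 0.112, "2": 0.020, "3": 0.216, "4": 0.440, "5": 0.212}
  },
  "dlcn_class_probs": {
    "FH_Mneg": {"<3": 0.007, "possible": 0.213, "probable": 0.536, "definite": 0.244},
    "FH_Mpos": {"<3": 0.012, "possible": 0.109, "probable": 0.440, "definite": 0.439}
  },
  "age": {"FH_Mneg": {"mean": 46.4, "sd": 12.4}, "FH_Mpos": {"mean": 42.3, "sd": 13.7}},
  "sex_male_prob": {"FH_Mneg": 0.464, "FH_Mpos": 0.452},
  "missing_rate": {"EUR": 0.0, "FH_Mneg": 0.004, "FH_Mpos": 0.004},
  "seed": 0
}
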