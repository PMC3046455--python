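[
  {"name": "10q26-rs2981582", "gene_label": "FGFR2", "alleles": ["C", "T"], "risk_allele": "T", "risk_allele_freq": 0.38, "per_allele_or": 1.22},
  {"name": "8q24-rs13281615", "gene_label": "intergenic", "alleles": ["A", "G"], "risk_allele": "G", "risk_allele_freq": 0.41, "per_allele_or": 1.12},
  {"name": "11p15-rs3817198", "gene_label": "LSP1", "alleles": ["T", "C"], "risk_allele": "C", "risk_allele_freq": 0.31, "per_allele_or": 1.08},
  {"name": "5q11-rs889312", "gene_label": "MAP3K1", "alleles": ["A", "C"], "risk_allele": "C", "risk_allele_freq": 0.28, "per_allele_or": 1.11},
  {"name": "16q12-rs3803662", "gene_label": "TOX3/TNRC9", "alleles": ["C", "T"], "risk_allele": "T", "risk_allele_freq": 0.26, "per_allele_or": 1.23},
  {"name": "2q35-rs13387042", "gene_label": "intergenic", "alleles": ["G", "A"], "risk_allele": "A", "risk_allele_freq": 0.52, "per_allele_or": 1.14},
  {"name": "5p12-rs10941679", "gene_label": "MRPS30", "alleles": ["A", "G"], "risk_allele": "G", "risk_allele_freq": 0.26, "per_allele_or": 1.12},
  {"name": "17q23-rs6504950", "gene_label": "COX11/STXBP4", "alleles": ["G", "A"], "risk_allele": "A", "risk_allele_freq": 0.28, "per_allele_or": 0.95},
  {"name": "3p24-rs4973768", "gene_label": "SLC4A7/NEK10", "alleles": ["C", "T"], "risk_allele": "T", "risk_allele_freq": 0.46, "per_allele_or": 1.11},
  {"name": "2q33-rs17468277", "gene_label": "CASP8", "alleles": ["C", "T"], "risk_allele": "T", "risk_allele_freq": 0.13, "per_allele_or": 0.94},
  {"name": "19q13-rs1982073", "gene_label": "TGFB1", "alleles": ["T", "C"], "risk_allele": "C", "risk_allele_freq": 0.38, "per_allele_or": 1.04},
  {"name": "6q25-rs3020314", "gene_label": "ESR1", "alleles": ["T", "C"], "risk_allele": "C", "risk_allele_freq": 0.32, "per_allele_or": 1.03}
]
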