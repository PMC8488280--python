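{
  "provenance": "published",
  "cutoff": 1.35,
  "pairs": [
    {"gene1": "ARSB", "gene2": "BIRC5", "weight": 0.2155943},
    {"gene1": "BAK1", "gene2": "CX3CL1", "weight": -0.051255},
    {"gene1": "BAX", "gene2": "CX3CL1", "weight": -0.199284},
    {"gene1": "BCL2", "gene2": "SPHK1", "weight": 0.0516312},
    {"gene1": "BIRC5", "gene2": "MAP2K7", "weight": -0.225825},
    {"gene1": "BIRC5", "gene2": "TSC1", "weight": -0.142442},
    {"gene1": "CCL2", "gene2": "CX3CL1", "weight": -0.275192},
    {"gene1": "CCR2", "gene2": "SPHK1", "weight": 0.3833014},
    {"gene1": "CDKN2A", "gene2": "MAPK9", "weight": -0.319519},
    {"gene1": "FADD", "gene2": "HSPB8", "weight": -0.151957}
  ],
  "metadata": {
    "description": "Published 10-pair autophagy gene-pair index (ATGPI) for early-stage lung adenocarcinoma, with the published risk cutoff."
  }
}
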