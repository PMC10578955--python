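{
  "name": "svm_top5",
  "description": "Five-feature generating set for TOT maps (SVM preset)",
  "features": [
    "ASD_anderson_glszm_ZoneEntropy",
    "SI_gldm_SmallDependenceLowGrayLevelEmphasis",
    "SS_gldm_SmallDependenceHighGrayLevelEmphasis",
    "AAC_gaussian_gldm_DependenceVariance",
    "AAC_anderson_gldm_SmallDependenceEmphasis"
  ]
}
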