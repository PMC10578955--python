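{
  "name": "knn_top5",
  "description": "Five-feature generating set for TOT maps (k-NN preset)",
  "features": [
    "ASD_anderson_glszm_ZoneEntropy",
    "ASD_anderson_glrlm_LongRunLowGrayLevelEmphasis",
    "ASD_anderson_glszm_LargeAreaLowGrayLevelEmphasis",
    "ASD_gaussian_gldm_LowGrayLevelEmphasis",
    "SS_glszm_SmallAreaLowGrayLevelEmphasis"
  ]
}
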