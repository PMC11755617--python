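antibody,species,cl_ml_h_kg,scf_pct,provenance
alirocumab,rat,0.488,66.6,de_novo_rat_study
alirocumab,monkey,0.352,75.1,internal
alirocumab,human,0.18,86.0,regulatory_label
canakinumab,rat,0.189,58.4,de_novo_rat_study
canakinumab,monkey,0.45,60.0,internal
canakinumab,human,0.11,67.0,regulatory_label
guselkumab,rat,0.38,63.7,de_novo_rat_study
guselkumab,monkey,0.42,87.5,internal
guselkumab,human,0.19,49.0,regulatory_label
secukinumab,rat,0.137,66.7,de_novo_rat_study
secukinumab,monkey,0.1,78.0,internal
secukinumab,human,0.11,66.0,regulatory_label
tabalumab,rat,0.227,105.2,de_novo_rat_study
tabalumab,monkey,0.17,101.0,internal
tabalumab,human,0.08,57.0,internal
ustekinumab,rat,0.21,70.6,de_novo_rat_study
ustekinumab,monkey,0.16,95.0,internal
ustekinumab,human,0.11,67.8,regulatory_label
bevacizumab,rat,0.275,69.0,internal
bevacizumab,monkey,0.223,98.0,internal
bevacizumab,human,0.14,,regulatory_label
ocrelizumab,rat,0.33,,internal
ocrelizumab,human,0.13,,regulatory_label
risankizumab,rat,0.204,74.8,de_novo_rat_study
risankizumab,monkey,0.24,71.8,internal
risankizumab,human,0.18,89.0,regulatory_label
mAb 1,rat,0.21,69.0,internal
mAb 1,monkey,0.21,84.0,internal
mAb 1,human,0.17,53.0,internal
mAb 2,rat,0.26,,internal
mAb 2,monkey,0.225,74.0,internal
mAb 2,human,0.16,52.0,internal
mAb 3,rat,0.25,59.0,internal
mAb 3,monkey,0.79,43.0,internal
mAb 3,human,0.26,40.0,internal
mAb 4,rat,0.366,103.4,de_novo_rat_study
mAb 4,monkey,0.32,,internal
mAb 4,human,0.26,,internal
mAb 5,rat,0.261,44.7,de_novo_rat_study
mAb 5,monkey,0.23,,internal
mAb 5,human,0.15,,internal
mAb 6,rat,0.285,42.5,de_novo_rat_study
mAb 6,monkey,0.38,,internal
mAb 6,human,0.13,,internal
mAb 7,rat,0.35,82.4,internal
mAb 7,monkey,0.1,76.6,internal
mAb 7,human,0.13,60.0,internal
mAb 8,rat,0.43,,internal
mAb 8,monkey,0.31,89.3,internal
mAb 8,human,0.135,,internal
mAb 9,rat,0.543,27.5,de_novo_rat_study
mAb 9,monkey,0.61,41.0,internal
mAb 9,human,0.49,22.0,internal
mAb 10,rat,0.45,33.0,internal
mAb 10,monkey,0.41,75.0,internal
mAb 10,human,0.17,9.0,internal
mAb 11,rat,0.293,,internal
mAb 11,monkey,0.203,,internal
mAb 11,human,0.273,,internal
mAb 12,rat,0.823,46.7,de_novo_rat_study
mAb 12,monkey,1.85,35.0,internal
mAb 12,human,0.73,,internal
mAb 13,rat,0.323,72.9,de_novo_rat_study
mAb 13,monkey,0.52,,internal
mAb 13,human,0.43,,internal
mAb 14,rat,0.424,40.6,de_novo_rat_study
mAb 14,monkey,0.52,112.0,internal
mAb 14,human,0.38,40.0,internal
mAb 15,rat,0.45,45.2,internal
mAb 15,monkey,0.35,83.1,internal
mAb 16,rat,0.15,,internal
mAb 16,monkey,0.18,79.1,internal
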