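category,variable,tissue_class,outcome,standardized_beta,p_value
nbv,whole_nbv,,global_cognition,0.330,0.003
nbv,whole_nbv,,processing_speed,0.361,0.002
nbv,whole_nbv,,mental_flexibility,0.286,0.016
nbv,whole_nbv,,verbal_fluency,0.171,0.153
nbv,whole_nbv,,verbal_memory,0.245,0.041
nbv,whole_nbv,,moca,0.421,0.001
nbv,whole_nbv,,ssqol,0.273,0.036
nbv,whole_nbv,,euroqol,0.200,0.115
nbv,gm_nbv,,global_cognition,0.167,0.109
nbv,gm_nbv,,processing_speed,0.109,0.321
nbv,gm_nbv,,mental_flexibility,0.111,0.312
nbv,gm_nbv,,verbal_fluency,0.147,0.177
nbv,gm_nbv,,verbal_memory,0.177,0.109
nbv,gm_nbv,,moca,0.339,0.001
nbv,gm_nbv,,ssqol,0.084,0.485
nbv,gm_nbv,,euroqol,-0.016,0.888
nbv,wm_nbv,,global_cognition,0.199,0.036
nbv,wm_nbv,,processing_speed,0.283,0.004
nbv,wm_nbv,,mental_flexibility,0.202,0.043
nbv,wm_nbv,,verbal_fluency,0.049,0.627
nbv,wm_nbv,,verbal_memory,0.101,0.320
nbv,wm_nbv,,moca,0.142,0.150
nbv,wm_nbv,,ssqol,0.213,0.051
nbv,wm_nbv,,euroqol,0.225,0.034
wmh,wmh_lesion_load,,global_cognition,-0.288,0.001
wmh,wmh_lesion_load,,processing_speed,-0.312,0.001
wmh,wmh_lesion_load,,mental_flexibility,-0.245,0.009
wmh,wmh_lesion_load,,verbal_fluency,-0.240,0.011
wmh,wmh_lesion_load,,verbal_memory,-0.132,0.170
wmh,wmh_lesion_load,,moca,-0.196,0.035
wmh,wmh_lesion_load,,ssqol,-0.249,0.015
wmh,wmh_lesion_load,,euroqol,-0.248,0.013
lacunes,lacune_count,,global_cognition,-0.357,0.001
lacunes,lacune_count,,processing_speed,-0.389,0.001
lacunes,lacune_count,,mental_flexibility,-0.268,0.006
lacunes,lacune_count,,verbal_fluency,-0.286,0.003
lacunes,lacune_count,,verbal_memory,-0.233,0.018
lacunes,lacune_count,,moca,-0.333,0.001
lacunes,lacune_count,,ssqol,-0.323,0.002
lacunes,lacune_count,,euroqol,-0.195,0.062
dti,fa_median_nawm,nawm,global_cognition,0.352,0.001
dti,fa_median_nawm,nawm,processing_speed,0.247,0.009
dti,fa_median_nawm,nawm,mental_flexibility,0.338,0.001
dti,fa_median_nawm,nawm,verbal_fluency,0.374,0.001
dti,fa_median_nawm,nawm,verbal_memory,0.167,0.081
dti,fa_median_nawm,nawm,moca,0.332,0.001
dti,fa_median_nawm,nawm,ssqol,0.196,0.058
dti,fa_median_nawm,nawm,euroqol,0.253,0.011
dti,md_peak_height_nawm,nawm,global_cognition,0.267,0.005
dti,md_peak_height_nawm,nawm,processing_speed,0.186,0.063
dti,md_peak_height_nawm,nawm,mental_flexibility,0.241,0.016
dti,md_peak_height_nawm,nawm,verbal_fluency,0.275,0.006
dti,md_peak_height_nawm,nawm,verbal_memory,0.160,0.115
dti,md_peak_height_nawm,nawm,moca,0.262,0.007
dti,md_peak_height_nawm,nawm,ssqol,0.170,0.121
dti,md_peak_height_nawm,nawm,euroqol,0.244,0.021
dti,fa_median_wm,wm,global_cognition,0.371,0.001
dti,fa_median_wm,wm,processing_speed,0.282,0.002
dti,fa_median_wm,wm,mental_flexibility,0.354,0.001
dti,fa_median_wm,wm,verbal_fluency,0.375,0.001
dti,fa_median_wm,wm,verbal_memory,0.174,0.067
dti,fa_median_wm,wm,moca,0.329,0.001
dti,fa_median_wm,wm,ssqol,0.213,0.037
dti,fa_median_wm,wm,euroqol,0.267,0.007
dti,md_peak_height_wm,wm,global_cognition,0.303,0.001
dti,md_peak_height_wm,wm,processing_speed,0.247,0.011
dti,md_peak_height_wm,wm,mental_flexibility,0.273,0.005
dti,md_peak_height_wm,wm,verbal_fluency,0.293,0.003
dti,md_peak_height_wm,wm,verbal_memory,0.162,0.101
dti,md_peak_height_wm,wm,moca,0.262,0.006
dti,md_peak_height_wm,wm,ssqol,0.218,0.042
dti,md_peak_height_wm,wm,euroqol,0.291,0.005
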