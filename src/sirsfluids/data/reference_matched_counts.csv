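group,outcome,events_saline,events_balanced,n_saline,n_balanced,or_printed,ci_low_printed,ci_high_printed
administrative,cardiac,135,69,1558,1558,0.488,0.362,0.659
administrative,hemorrhage,11,8,1558,1558,0.726,0.291,1.809
administrative,infectious,158,94,1558,1558,0.569,0.436,0.742
administrative,gastrointestinal,85,80,1558,1558,0.938,0.685,1.284
administrative,neurologic,18,13,1558,1558,0.72,0.352,1.474
administrative,acute_renal_failure,68,52,1558,1558,0.757,0.524,1.093
administrative,respiratory_failure,85,54,1558,1558,0.622,0.439,0.882
administrative,new_organ_failure,142,111,1558,1558,0.765,0.59,0.991
clinical,hospital_mortality,51,16,1558,1558,0.307,0.174,0.54
clinical,readmission_30,148,119,1558,1558,0.788,0.612,1.014
clinical,readmission_60,211,170,1558,1558,0.782,0.63,0.97
clinical,readmission_90,258,196,1558,1558,0.725,0.593,0.886
cardiac,dysrhythmia,166,107,1558,1558,0.618,0.48,0.797
cardiac,cardiac_stress,100,32,1558,1558,0.306,0.204,0.458
cardiac,heart_failure,63,23,1558,1558,0.356,0.219,0.576
hemorrhage,coagulopathy,150,106,1558,1558,0.67,0.516,0.87
hemorrhage,transfusion,46,36,1558,1558,0.777,0.5,1.209
hemorrhage,bleeding,313,311,1558,1558,0.992,0.832,1.182
infectious,pneumonia,94,33,1558,1558,0.337,0.225,0.504
infectious,sepsis,164,88,1558,1558,0.509,0.389,0.666
infectious,urinary_tract_infection,92,73,1558,1558,0.783,0.571,1.074
infectious,line_infection,12,0,1558,1558,,,
gastrointestinal,cholecystitis,74,55,1558,1558,0.734,0.514,1.048
renal,acute_kidney_injury,85,69,1558,1558,0.803,0.580,1.112
electrolyte,low_magnesium_replacement,68,33,1558,1558,0.474,0.311,0.723
electrolyte,high_magnesium,68,53,1558,1558,0.772,0.535,1.113
electrolyte,low_potassium_replacement,220,117,1558,1558,0.494,0.39,0.625
electrolyte,high_potassium,147,107,1558,1558,0.708,0.546,0.918
electrolyte,low_sodium,614,477,1558,1558,0.678,0.585,0.787
electrolyte,high_sodium,109,94,1558,1558,0.854,0.642,1.135
electrolyte,low_calcium_replacement,20,15,1558,1558,0.748,0.381,1.466
acidosis,lactic_acidosis,11,4,1558,1558,0.362,0.115,1.139
acidosis,metabolic_acidosis,43,19,1558,1558,0.435,0.252,0.75
acidosis,hyperchloremic_acidosis,54,19,1558,1558,0.344,0.203,0.583
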