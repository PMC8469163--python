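metabolite,vip,p_paired,correlation_shift,regulation
3-Hydroxybutyrate,2.44,0.072,>1,up
Trimethylamine N-oxide,2.07,0.001,NA,up
Methanol,1.43,0.050,>1,up
Hippurate,1.34,0.002,>1,up
Acetate,1.33,0.400,NA,up
Valine,1.29,0.050,>1,up
3-Hydroxyisobutyrate,1.22,0.002,>1,up
Alanine,1.08,NA,NA,down
Leucine,1.06,0.050,NA,up
4-Hydroxyphenylacetate,0.84,0.027,>1,up
Betaine,0.06,0.830,>1,up
Creatine,0.92,0.049,>1,up
Creatine phosphate,0.44,0.086,>1,down
Creatinine,0.85,0.010,NA,up
Dimethyl sulfone,0.31,0.170,>1,up
Methionine,0.43,NA,>1,up
Myo-Inositol,0.62,0.050,NA,up
Phenylalanine,0.81,0.050,NA,up
Propionate,0.79,0.011,>1,up
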