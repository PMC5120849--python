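site,fraction,form,a,b,c,se_a,se_b,se_c,unit_scale
Kerloch,calluna,gompertz,22.96,3.22,0.88,0.89,0.46,0.01,1.0
Kerloch,litter,gompertz,20.65,2.61,0.89,0.79,0.31,0.01,1.0
Moor House,calluna,gompertz,7.94,8.07,0.78,0.80,3.55,0.04,1.0
Moor House,litter,gompertz,8.90,1.70,0.70,0.70,10.83,0.90,1.0
Howden,calluna,loglinear,-0.93,1.15,,0.05,0.02,0.0,1.0
Howden,litter,loglinear,3.86,1.10,,0.04,0.02,0.0,0.01
Dorset,calluna,gompertz,20.15,3.58,0.86,0.62,0.53,0.01,1.0
Dorset,litter,gompertz,28.38,8.67,0.86,2.96,6.11,0.04,1.0
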