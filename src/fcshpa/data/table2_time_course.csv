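arm,time_min,fcs_pct,fcs_dev,elisa_pct_to_fcs,elisa_dev
basal,0,0.00,1.28,-3.39,2.91
basal,1320,7.48,1.29,-1.86,2.16
crh,1,4.79,1.82,-0.91,3.11
crh,5,8.08,1.39,-1.16,3.35
crh,15,8.62,1.36,2.77,3.29
crh,30,9.51,1.43,4.05,2.96
crh,60,11.18,1.62,4.61,2.12
crh,120,15.50,1.86,2.97,2.27
crh,1320,24.74,2.32,2.63,2.31
crh_cortisol,1,1.16,2.03,-3.77,3.58
crh_cortisol,5,2.08,2.88,-3.68,4.12
crh_cortisol,15,3.02,2.85,-2.97,3.38
crh_cortisol,30,4.94,1.75,-1.80,2.44
crh_cortisol,60,6.80,1.63,-0.81,3.01
crh_cortisol,120,9.40,2.31,1.52,2.33
crh_cortisol,1320,12.23,2.07,3.10,2.41
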