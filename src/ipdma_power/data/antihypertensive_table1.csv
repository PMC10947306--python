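trial_id,n_control,n_treatment,e_control,e_treatment,f_control,f_treatment,cov_kind,cov_prop_z1_control_pct,cov_prop_z1_treatment_pct,cov_mean_control,cov_mean_treatment,cov_sd_control,cov_sd_treatment,cov_unit_scale,covariate
1,750,780,13,9,2.92,3.14,binary,70.00,69.36,,,,,1,sex
2,199,150,28,27,4.43,4.79,binary,37.19,32.67,,,,,1,sex
3,82,90,29,32,4.13,4.56,binary,20.73,25.56,,,,,1,sex
4,2371,2427,82,81,4.91,4.92,binary,53.73,54.64,,,,,1,sex
5,3445,3546,69,73,4.97,4.95,binary,59.01,58.83,,,,,1,sex
6,1337,1314,199,178,5.75,5.79,binary,41.81,41.25,,,,,1,sex
7,2371,2365,242,213,4.31,4.34,binary,42.68,43.72,,,,,1,sex
8,131,137,7,4,1.93,1.98,binary,24.43,27.01,,,,,1,sex
9,1139,1252,82,61,2.54,2.80,binary,63.65,65.02,,,,,1,sex
10,2297,2398,137,123,2.49,2.50,binary,33.83,32.53,,,,,1,sex
1,750,780,13,9,2.92,3.14,continuous,,,42.36,42.17,5.34,5.39,10,age
2,199,150,28,27,4.43,4.79,continuous,,,69.57,69.71,5.39,5.18,10,age
3,82,90,29,32,4.13,4.56,continuous,,,74.11,72.64,8.69,7.99,10,age
4,2371,2427,82,81,4.91,4.92,continuous,,,41.54,41.58,5.48,5.53,10,age
5,3445,3546,69,73,4.97,4.95,continuous,,,45.17,45.38,5.86,6.00,10,age
6,1337,1314,199,178,5.75,5.79,continuous,,,70.43,70.41,2.72,2.74,10,age
7,2371,2365,242,213,4.31,4.34,continuous,,,71.54,71.64,6.68,6.72,10,age
8,131,137,7,4,1.93,1.98,continuous,,,75.90,76.00,3.95,3.75,10,age
9,1139,1252,82,61,2.54,2.80,continuous,,,66.77,66.42,5.67,5.34,10,age
10,2297,2398,137,123,2.49,2.50,continuous,,,70.21,70.26,6.67,6.73,10,age
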