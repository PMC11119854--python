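range,n_control,n_oa,mean_control,se_control,mean_oa,se_oa,flagged_control,flagged_pct_control,flagged_oa,flagged_pct_oa
95-100,17,11,48.5,1.6,44.1,1.0,1,5,7,64
90-95,3,5,47.3,3.5,40.8,0.8,0,0,4,80
85-90,1,3,37.0,0.0,35.5,1.2,1,100,3,100
<85,3,9,36.6,2.7,30.1,2.6,2,67,8,89
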