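period,group,site,mean,se
baseline,control,brain,50.4,2.7
post1h,control,brain,48.3,2.6
fio2_40,control,brain,47.5,2.5
fio2_30,control,brain,46.3,2.6
fio2_21,control,brain,41.2,3.2
baseline,oa,brain,54.6,2.6
post1h,oa,brain,44.9,1.4
fio2_40,oa,brain,42.6,0.7
fio2_30,oa,brain,38.4,1.0
fio2_21,oa,brain,27.9,2.6
baseline,control,gut,66.5,6.2
post1h,control,gut,57.8,7.4
fio2_40,control,gut,57.7,5.8
fio2_30,control,gut,53.5,4.1
fio2_21,control,gut,46.5,4.7
baseline,oa,gut,61.9,4.4
post1h,oa,gut,53.3,2.7
fio2_40,oa,gut,50.6,2.0
fio2_30,oa,gut,44.7,2.3
fio2_21,oa,gut,32.0,2.5
baseline,control,kidney,47.7,6.0
post1h,control,kidney,48.6,2.7
fio2_40,control,kidney,49.6,2.4
fio2_30,control,kidney,48.6,2.5
fio2_21,control,kidney,45.4,2.8
baseline,oa,kidney,60.6,5.0
post1h,oa,kidney,52.6,5.7
fio2_40,oa,kidney,50.4,4.2
fio2_30,oa,kidney,47.0,4.0
fio2_21,oa,kidney,34.0,3.2
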