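variable,group,period,mean,se
weight,control,baseline,2.13,0.09
weight,oa,baseline,2.177,0.146
hr,control,baseline,155.7,14.3
hr,control,post1h,155.5,14.3
hr,control,fio2_40,157.8,17.1
hr,control,fio2_30,154.8,21.0
hr,control,fio2_21,171.2,25.7
hr,oa,baseline,157.9,5.0
hr,oa,post1h,154.4,10.7
hr,oa,fio2_40,162.0,10.7
hr,oa,fio2_30,161.0,15.7
hr,oa,fio2_21,187.6,18.0
mbp,control,baseline,84.3,4.3
mbp,control,post1h,81.7,4.8
mbp,control,fio2_40,78.8,5.4
mbp,control,fio2_30,74.8,5.5
mbp,control,fio2_21,74.0,7.1
mbp,oa,baseline,77.3,3.3
mbp,oa,post1h,70.7,3.0
mbp,oa,fio2_40,68.4,3.3
mbp,oa,fio2_30,71.6,5.6
mbp,oa,fio2_21,70.3,7.1
sbp,control,baseline,113.2,5.6
sbp,control,post1h,109.7,5.1
sbp,control,fio2_40,106.5,5.1
sbp,control,fio2_30,101.6,5.2
sbp,control,fio2_21,101.0,7.8
sbp,oa,baseline,102.3,4.2
sbp,oa,post1h,94.9,3.2
sbp,oa,fio2_40,94.4,4.9
sbp,oa,fio2_30,92.9,5.3
sbp,oa,fio2_21,93.6,7.2
dbp,control,baseline,65.3,3.1
dbp,control,post1h,64.7,5.6
dbp,control,fio2_40,62.2,6.2
dbp,control,fio2_30,59.6,6.7
dbp,control,fio2_21,58.4,7.5
dbp,oa,baseline,59.9,2.6
dbp,oa,post1h,54.1,2.8
dbp,oa,fio2_40,55.6,5.5
dbp,oa,fio2_30,56.9,5.7
dbp,oa,fio2_21,54.7,7.0
cvp,control,baseline,7.7,0.6
cvp,control,post1h,7.5,0.3
cvp,control,fio2_40,7.3,0.4
cvp,control,fio2_30,7.2,0.5
cvp,control,fio2_21,7.2,0.6
cvp,oa,baseline,6.4,0.5
cvp,oa,post1h,6.1,0.4
cvp,oa,fio2_40,5.9,0.4
cvp,oa,fio2_30,5.9,0.4
cvp,oa,fio2_21,5.9,0.4
temp,control,baseline,36.7,0.2
temp,control,post1h,37.9,0.3
temp,control,fio2_40,37.5,0.2
temp,control,fio2_30,37.4,0.2
temp,control,fio2_21,37.1,0.2
temp,oa,baseline,36.7,0.2
temp,oa,post1h,37.7,0.3
temp,oa,fio2_40,37.7,0.2
temp,oa,fio2_30,37.6,0.2
temp,oa,fio2_21,37.5,0.2
pi,control,baseline,0.72,0.11
pi,control,post1h,0.80,0.14
pi,control,fio2_40,0.80,0.13
pi,control,fio2_30,0.79,0.15
pi,control,fio2_21,0.81,0.15
pi,oa,baseline,0.90,0.14
pi,oa,post1h,0.56,0.07
pi,oa,fio2_40,0.72,0.09
pi,oa,fio2_30,0.56,0.06
pi,oa,fio2_21,0.57,0.08
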