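animal_id,group,sao2,rcso2,baseline
c1,control,97.5,37.5,50.0
c2,control,97.5,46.0,50.0
c3,control,97.5,46.0,50.0
c4,control,97.5,46.0,50.0
c5,control,97.5,46.0,50.0
c6,control,97.5,46.0,50.0
c1,control,97.5,46.0,50.0
c2,control,97.5,46.0,50.0
c3,control,97.5,46.0,50.0
c4,control,97.5,46.0,50.0
c5,control,97.5,46.0,50.0
c6,control,97.5,46.0,50.0
c1,control,97.5,46.0,50.0
c2,control,97.5,46.0,50.0
c3,control,97.5,46.0,50.0
c4,control,97.5,46.0,50.0
c5,control,97.5,46.0,50.0
c6,control,92.5,46.0,50.0
c1,control,92.5,46.0,50.0
c2,control,92.5,46.0,50.0
c3,control,87.5,37.5,50.0
c4,control,82.0,37.5,50.0
c5,control,82.0,37.5,50.0
c6,control,82.0,46.0,50.0
o1,oa,97.5,40.5,54.0
o2,oa,97.5,40.5,54.0
o3,oa,97.5,40.5,54.0
o4,oa,97.5,40.5,54.0
o5,oa,97.5,40.5,54.0
o6,oa,97.5,40.5,54.0
o7,oa,97.5,40.5,54.0
o1,oa,97.5,49.7,54.0
o2,oa,97.5,49.7,54.0
o3,oa,97.5,49.7,54.0
o4,oa,97.5,49.7,54.0
o5,oa,92.5,40.5,54.0
o6,oa,92.5,40.5,54.0
o7,oa,92.5,40.5,54.0
o1,oa,92.5,40.5,54.0
o2,oa,92.5,49.7,54.0
o3,oa,87.5,40.5,54.0
o4,oa,87.5,40.5,54.0
o5,oa,87.5,40.5,54.0
o6,oa,82.0,40.5,54.0
o7,oa,82.0,40.5,54.0
o1,oa,82.0,40.5,54.0
o2,oa,82.0,40.5,54.0
o3,oa,82.0,40.5,54.0
o4,oa,82.0,40.5,54.0
o5,oa,82.0,40.5,54.0
o6,oa,82.0,40.5,54.0
o7,oa,82.0,49.7,54.0
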