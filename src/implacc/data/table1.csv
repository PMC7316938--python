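patient_no,template_fit,location_fdi,implant_length_mm,angular_deg,global_mm,lateral_mm,depth_mm
1,Good,13,15,5.0,1.0,0.8,0.6
1,Good,23,15,7.7,1.2,0.6,1.0
2,Good,13,13,5.2,1.0,0.9,0.4
2,Good,23,13,4.5,0.9,0.5,0.7
3,Good,12,13,4.2,0.4,0.3,0.3
3,Good,15,13,8.9,0.4,0.2,0.4
3,Good,22,13,0.6,1.1,0.4,1.0
3,Good,25,13,4.1,0.9,0.4,0.9
4,Good,13,13,8.9,2.6,2.6,0.2
4,Good,23,13,13.0,1.9,1.9,0.1
5,Good,13,15,7.9,0.4,0.4,0.2
5,Good,23,15,8.7,0.5,0.5,0.1
6,Bad,13,15,9.3,1.1,0.8,0.7
6,Bad,23,NA,NA,NA,NA,NA
7,Good,13,13,8.7,1.3,0.8,1.0
7,Good,23,13,6.2,0.9,0.6,0.6
8,Good,13,15,10.8,1.2,1.0,0.7
8,Good,23,15,8.2,1.2,0.6,1.2
9,Good,13,13,7.6,1.5,0.9,1.2
9,Good,23,13,12.5,0.4,0.3,0.2
10,Good,13,13,13.0,1.0,1.0,0.1
10,Good,23,13,1.5,2.0,0.8,1.8
11,Good,13,13,2.1,1.0,1.0,0.1
11,Good,23,13,8.0,0.7,0.6,0.3
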