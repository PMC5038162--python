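id,name,length_cm,r_top_cm,r_bottom_cm,daughter_1,daughter_2,bed_root_radius_cm
1,ascending_aorta,7.0,1.25,1.14,2,3,
2,anonyma,3.5,0.70,0.70,4,5,
3,aortic_arch_a,1.8,1.14,1.11,6,7,
4,r_subclavian_brachial,43.0,0.44,0.28,,,0.28
5,r_carotid,17.0,0.29,0.28,,,0.28
6,l_carotid,19.0,0.29,0.28,,,0.28
7,aortic_arch_b,1.0,1.11,1.09,8,9,
8,l_subclavian_brachial,44.6,0.44,0.28,,,0.28
9,thoracic_aorta_a,5.5,1.09,1.02,10,,
10,thoracic_aorta_b,13.3,1.02,0.85,11,12,
11,celiac,3.0,0.33,0.30,,,0.30
12,abdominal_aorta_a,2.0,0.85,0.83,13,14,
13,sup_mesenteric,5.0,0.33,0.33,,,0.33
14,abdominal_aorta_b,2.0,0.83,0.80,15,16,
15,r_renal,3.0,0.28,0.25,,,0.25
16,abdominal_aorta_c,1.0,0.80,0.79,17,18,
17,l_renal,3.0,0.28,0.25,,,0.25
18,abdominal_aorta_d,6.0,0.79,0.73,19,20,
19,inf_mesenteric,4.0,0.20,0.18,,,0.18
20,abdominal_aorta_e,3.0,0.73,0.70,21,22,
21,r_iliac,5.8,0.45,0.43,23,,
22,l_iliac,5.8,0.45,0.43,24,,
23,r_femoral,14.5,0.43,0.26,,,0.26
24,l_femoral,14.5,0.43,0.26,,,0.26
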