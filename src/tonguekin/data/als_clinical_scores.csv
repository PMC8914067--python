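patient_id,onset_type,alsfrs_r_total,alsfrs_r_bulbar,cns_bfs,disease_duration_months
1,limb,25,7,53,13
2,limb,45,12,22,26
3,limb,37,12,21,186
4,limb,41,11,29,11
5,limb,41,9,31,11
6,limb,40,10,32,11
7,limb,42,12,22,18
8,limb,14,8,28,2
9,bulbar,47,11,28,6
10,bulbar,33,7,62,33
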