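patient_id,comparison_group,feature,value
1,controls,n_sweeps,16
1,controls,mean_sweep_duration_s,0.30
1,controls,n_errors,1
4,controls,n_sweeps,32
4,controls,mean_sweep_duration_s,0.17
4,controls,n_errors,4
5,controls,n_sweeps,17
5,controls,mean_sweep_duration_s,0.30
5,controls,n_errors,3
6,controls,n_sweeps,18
6,controls,mean_sweep_duration_s,0.28
6,controls,n_errors,6
8,controls,n_sweeps,15
8,controls,mean_sweep_duration_s,0.33
8,controls,n_errors,4
9,controls,n_sweeps,12
9,controls,mean_sweep_duration_s,0.45
9,controls,n_errors,4
10,controls,n_sweeps,22
10,controls,mean_sweep_duration_s,0.22
10,controls,n_errors,3
9,limb_onset,n_sweeps,12
9,limb_onset,mean_sweep_duration_s,0.45
9,limb_onset,n_errors,4
10,limb_onset,n_sweeps,22
10,limb_onset,mean_sweep_duration_s,0.22
10,limb_onset,n_errors,3
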