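group,feature,mean,sd,n
controls,n_sweeps,27,11.71,16
controls,mean_sweep_duration_s,0.23,0.13,16
controls,n_errors,2.44,3.25,16
limb_onset,n_sweeps,19.13,7.22,8
limb_onset,mean_sweep_duration_s,0.30,0.13,8
limb_onset,n_errors,2.75,2.19,8
all_patients,n_sweeps,18.70,6.85,10
all_patients,mean_sweep_duration_s,0.30,0.11,10
all_patients,n_errors,2.90,1.97,10
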