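# SYNTHETIC demonstration data: invented 2x2 counts for three
# placebo-controlled LMWH prophylaxis trials, constructed so the pooled
# random-effects relative risk of VTE is approximately 0.49. These are NOT
# the counts of any real trial.
study_id,events_tx,n_tx,events_ctrl,n_ctrl
synthetic_trial_A,24,1000,50,1000
synthetic_trial_B,18,800,37,800
synthetic_trial_C,30,1200,61,1220
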