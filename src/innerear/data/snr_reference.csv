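sequence,snr_template,snr_individual_mean,snr_individual_sd
T2,4.02,2.49,0.20
CISS,3.26,1.73,0.14
T1,3.13,1.85,0.28
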