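expression,rt_mean_ms,rt_sd_ms
happiness,823,80
surprise,958,116
anger,1154,148
sadness,1239,210
disgust,1149,235
fear,1429,273
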