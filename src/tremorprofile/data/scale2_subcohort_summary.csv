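statistic,age,v1_ftmtrs_a,v1_ftmtrs_b,v1_ftmtrs_c,v2_ftmtrs_a,v2_ftmtrs_b,v2_ftmtrs_c,days
mean,47,1.6,6.6,14.6,1.5,7.6,16.4,153.1
max,67,4.0,20.0,24.0,4.0,20.0,24.0,267.0
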