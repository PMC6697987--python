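subject_id,sex,age,visit,ftmtrs_a,ftmtrs_b,ftmtrs_c,days_since_visit1
P01,F,57,1,3,18,24,0
P01,F,57,2,4,17,24,216
P02,F,44,1,4,20,24,0
P03,M,52,1,2,5,8,0
P03,M,52,2,1,5,11,246
P04,F,57,1,2,5,14,0
P04,F,57,2,2,6,19,194
P05,F,34,1,2,6,20,0
P05,F,34,2,2,6,19,222
P06,M,60,1,4,20,24,0
P06,M,60,2,4,20,24,209
P07,F,44,1,3,18,18,0
P07,F,44,2,2,13,23,192
P08,F,45,1,3,19,20,0
P08,F,45,2,2,10,24,381
P09,F,49,1,0,0,9,0
P09,F,49,2,0,0,10,206
P10,M,42,1,1,13,18,0
P10,M,42,2,1,20,24,155
P11,F,48,1,1,0,5,0
P11,F,48,2,1,1,5,189
P12,F,46,1,2,12,19,0
P12,F,46,2,1,9,19,101
P13,F,43,1,1,2,8,0
P13,F,43,2,1,1,9,267
P14,M,33,1,1,5,13,0
P14,M,33,2,1,5,14,225
P15,F,55,1,1,3,21,0
P16,F,48,1,1,2,16,0
P16,F,48,2,3,12,21,154
P17,M,50,1,0,1,11,0
P17,M,50,2,1,3,13,138
P18,M,31,1,2,1,16,0
P18,M,31,2,1,3,14,147
P19,F,45,1,1,1,6,0
P19,F,45,2,1,3,10,28
P20,F,30,1,1,3,12,0
P20,F,30,2,1,4,11,21
P21,F,31,1,0,0,3,0
P21,F,31,2,1,1,4,35
P22,F,44,1,2,19,20,0
P22,F,44,2,2,13,22,27
P23,F,67,1,2,9,20,0
P23,F,67,2,2,11,19,16
P24,F,34,1,0,0,1,0
P24,F,34,2,1,0,6,12
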