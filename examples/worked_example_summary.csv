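stage,partition,n_control,n_treatment,mean_diff
1,1,45,45,3
1,2,45,45,2
1,3,45,45,0.8
1,4,45,45,0
2,1,60,60,3
2,2,60,60,2.4
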