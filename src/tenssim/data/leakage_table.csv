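channel,mean_mA,sd_mA
1,0.15,0.02
2,0.20,0.02
3,0.17,0.02
4,0.15,0.01
5,0.13,0.02
6,0.11,0.01
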