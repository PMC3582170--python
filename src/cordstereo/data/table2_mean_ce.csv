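compartment,mean_ce
Total,0.044
WM,0.046
GM,0.046
DH,0.052
VH,0.054
CC,0.053
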