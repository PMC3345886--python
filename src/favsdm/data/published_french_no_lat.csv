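variable,coefficient,inclusion_order
Alti,0.02967,6
Prec,-0.002588,3
HJul,-0.4211,4
SRad,-153.6,2
Temp,0.3106,1
DPre,0.08299,5
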