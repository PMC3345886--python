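variable,coefficient,inclusion_order
Alti,0.0021,6
Prec,0.00077,1
HJul,-0.1,4
SRad,0.013,8
TJan,0.43,7
Temp,-0.6,2
DPre,0.0027,3
Lati,1.13,5
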