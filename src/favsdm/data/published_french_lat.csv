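variable,coefficient,inclusion_order
Alti250,0.00248,1
Prec,-0.003152,3
SRad,-43.11,5
DPre,0.1059,2
Lati,-8.826,3
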