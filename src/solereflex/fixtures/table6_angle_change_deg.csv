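subject,heel,forefoot
S1,-1.98,2.37
S2,-1.41,0.51
S3,-1.08,0.89
S4,-1.15,1.42
S5,-0.46,0.61
S6,-2.45,0.89
S7,-1.81,1.15
S8,-1.44,1.14
S9,-0.97,0.91
S10,-0.51,0.82
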