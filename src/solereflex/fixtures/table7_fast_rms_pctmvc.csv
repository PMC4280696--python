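subject,heel_ta,heel_sol,forefoot_ta,forefoot_sol
S1,1.17,2.11,8.82,6.58
S2,0.49,6.68,0.46,2.63
S3,3.52,13.34,1.32,8.02
S4,7.86,6.75,3.31,2.65
S5,6.52,3.23,2.88,4.61
S6,13.78,2.16,17.00,1.96
S7,11.67,4.83,1.58,1.95
S8,1.73,4.87,1.65,4.39
S9,1.47,1.27,1.45,1.29
S10,11.19,8.36,0.67,1.88
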