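subject,heel_ta,heel_sol,forefoot_ta,forefoot_sol
S1,0.91,1.14,0.89,1.05
S2,0.46,3.12,0.89,2.30
S3,1.19,3.42,1.20,4.02
S4,3.21,2.77,2.48,2.21
S5,1.70,2.37,1.07,2.06
S6,4.41,2.02,3.26,2.10
S7,2.89,2.41,2.98,1.33
S8,1.51,2.73,1.53,2.38
S9,1.38,1.19,1.31,1.22
S10,3.50,1.85,0.52,1.01
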