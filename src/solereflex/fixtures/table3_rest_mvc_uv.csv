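subject,rest_ta,rest_sol,mvc_ta,mvc_sol
S1,1.16,1.11,162.81,126.52
S2,1.24,1.46,347.23,91.43
S3,1.86,1.52,211.12,54.08
S4,1.29,1.75,69.16,74.23
S5,1.07,1.03,255.32,31.28
S6,1.01,1.05,100.04,66.12
S7,1.15,1.58,220.45,115.57
S8,1.35,1.05,109.36,31.91
S9,1.04,1.18,97.78,50.26
S10,1.41,1.49,318.28,47.53
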