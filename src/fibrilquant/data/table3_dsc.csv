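group,transition_C_mean,transition_C_sd
Control,71.99,0.77
Control-CXL,74.55,0.25
Control-CXL+Col,73.84,0.72
COLG,71.22,0.20
COLG-CXL,74.31,0.53
COLG-CXL+Col,73.96,0.65
ChaseABC,70.70,0.68
ChaseABC-CXL,74.95,0.72
ChaseABC-CXL+Col,73.68,0.67
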