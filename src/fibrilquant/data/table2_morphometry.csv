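group,diameter_nm_mean,diameter_nm_sd,nn_distance_nm_mean,nn_distance_nm_sd,density_mean,density_sd
Control,40.67,0.92,72.3,0.89,18.0,0.47
Control-CXL,42.38,0.62,69.4,2.01,24.6,0.53
Control-CXL+Col,40.82,0.53,58.7,2.81,25.5,0.92
COLG,36.37,2.15,75.4,1.22,13.9,1.56
COLG-CXL,37.21,3.44,62.4,2.78,23.5,1.38
COLG-CXL+Col,37.03,2.18,60.7,3.22,24.2,1.42
ChaseABC,40.45,3.81,78.8,4.00,13.1,0.97
ChaseABC-CXL,41.55,2.02,63.8,4.67,25.0,2.06
ChaseABC-CXL+Col,41.57,1.53,61.8,4.13,25.7,3.22
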