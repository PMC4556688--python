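group,cct_um_mean,cct_um_sd,swelled_cct_um_mean,swelled_cct_um_sd
Control,362,12.0,718,7.0
Control-CXL,348,7.5,683,8.5
Control-CXL+Col,355,6.5,678,6.0
COLG,331,10.5,791,9.5
COLG-CXL,325,5.0,765,9.0
COLG-CXL+Col,338,8.5,722,7.5
ChaseABC,316,6.5,844,12.5
ChaseABC-CXL,235,13.0,663,10.5
ChaseABC-CXL+Col,265,10.0,552,11.0
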