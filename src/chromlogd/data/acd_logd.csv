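id,acd_log_d
W21,-2.13
W22,0.00
W23,1.13
W24,0.62
W25,0.66
W26,-2.80
W27,-1.41
W28,0.49
W29,0.85
W30,0.61
W31,1.22
W32,2.27
W33,-2.10
S1,-4.05
S2,-6.60
S3,-3.34
S4,-2.57
S5,-3.91
S6,-7.73
S7,-2.87
S8,-2.87
S9,-2.18
S10,-5.54
S11,-3.15
S12,-3.23
S13,-5.14
S14,-5.36
W1,-1.12
W20,3.20
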