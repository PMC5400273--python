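gene,threshold
EPO,7.10
ETS1,1.81
ENO1,1.00
PGK1,1.37
LDHA,1.20
TPI,1.14
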