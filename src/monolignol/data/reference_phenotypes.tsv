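genotype	height_cm	lignin_mg_per_g
Yanjiang	120.19	1011.11
FS	71.93	633.33
9901	153.69	341.11
FH	187.84	255.56
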