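allele	frequency
HLA-A*01:01	0.1520
HLA-A*02:01	0.2700
HLA-A*02:05	0.0110
HLA-A*02:06	0.0290
HLA-A*03:01	0.1350
HLA-A*11:01	0.0960
HLA-A*24:02	0.1150
HLA-B*07:02	0.0940
HLA-B*08:01	0.0800
HLA-B*15:01	0.0520
HLA-B*35:01	0.0550
HLA-B*44:02	0.0490
HLA-B*44:03	0.0410
HLA-C*04:01	0.1190
HLA-C*07:01	0.1290
HLA-C*07:02	0.1240
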