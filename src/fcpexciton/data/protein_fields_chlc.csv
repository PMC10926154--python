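atom,pigment,Fx_au,Fy_au,Fz_au
MG,chl_c1,-0.0056,0.0003,0.0354
MG,chl_c2,-0.0016,0.0031,-0.0102
NA,chl_c1,-0.0020,0.0115,0.0049
NA,chl_c2,0.0032,0.0220,0.0011
NB,chl_c1,0.0055,-0.0002,0.0056
NB,chl_c2,0.0178,-0.0055,-0.0044
NC,chl_c1,-0.0085,-0.0057,0.0054
NC,chl_c2,-0.0075,-0.0170,-0.0034
ND,chl_c1,-0.0108,0.0021,0.0033
ND,chl_c2,-0.0193,0.0103,0.0003
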