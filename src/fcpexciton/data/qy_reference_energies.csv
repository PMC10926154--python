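method,chl_a,chl_c1,chl_c2
TD-LC-DFTB (gas phase),2.197,2.249,2.224
TD-LC-DFT (gas phase),2.239,2.291,2.262
DFT/MRCI (gas phase),1.910,2.023,1.987
QM/MM MD (ether),2.065,2.082,2.073
QM/MM MD (acetone),2.049,2.060,2.050
experiment (ether),1.873,1.981,1.977
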