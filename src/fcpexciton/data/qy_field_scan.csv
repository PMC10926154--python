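direction,chl_a,chl_c1,chl_c2
none,2.243,2.289,2.263
+x,2.192,2.252,2.248
+y,2.268,2.037,2.035
+z,2.243,2.287,2.241
-x,2.249,2.295,2.243
-y,2.220,2.285,2.242
-z,2.239,2.287,2.278
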