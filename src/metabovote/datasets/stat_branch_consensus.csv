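var_id,mz,appearance_pct
Var54,595.165,90.91
Var50,293.212,100.00
Var49,328.155,100.00
Var48,203.18,100.00
Var47,433.114,100.00
Var46,279.232,90.91
Var45,423.093,90.91
Var44,328.155,90.91
Var43,342.171,100.00
Var42,258.244,72.73
Var31,585.145,100.00
Var19,258.244,90.91
Var09,195.087,81.82
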