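var_id,mz,appearance_pct
Var55,593.276,60
Var51,621.305,60
Var50,293.212,100
Var49,328.155,100
Var48,203.18,100
Var47,433.114,60
Var46,279.232,100
Var45,423.093,60
Var44,328.155,60
Var43,342.171,80
Var42,258.244,100
Var31,585.145,80
Var30,701.493,60
Var28,814.577,60
Var27,905.679,60
Var21,288.256,60
Var02,290.27,80
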