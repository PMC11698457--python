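var_id,compound_name
Var31,neomangiferin
Var42,
Var43,lirioferine
Var44,norisocorydine
Var45,mangiferin
Var46,"15,16-dihydrotanshinone I"
Var47,apigenin-7-O-galactopyranoside
Var48,
Var49,norisocorydine
Var50,
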