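>fam7_a
MKLTVKDLQRELAAARMWTRKDDGLMNLAQGDNKVL
>fam7_b
MKLTVKALQRELAAARMWTRRDDGLMNLAQGDNKVL
>fam7_c
MKLTVKDLQRELAATRMWTRKDDALMNLALGDSKVL
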