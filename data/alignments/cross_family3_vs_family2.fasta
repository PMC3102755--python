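>cdc34_toy
MKLTVKDLQRELAADDEDDESSDDENARMWTRSDDELMNLASGDEKVL
>fam2_a
MKLTVKDLQRELAA------------ARMWTRSDDELMNLASGDEKVL
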