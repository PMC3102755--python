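>fam2_a
MKLTVKDLQRELAAARMWTRSDDELMNLASGDEKVL
>fam2_b
MKLTVRDLQRELAAARMWTRTDDELMNLASGDEKVL
>fam2_c
MKLTVKDLQREVAAARMWTRADDELMNLASGDDKVL
>fam2_d
MRLTVKDLQRELAAARMWTRSDDDLMNLANGDEKVL
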