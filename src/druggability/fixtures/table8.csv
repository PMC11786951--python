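target,molecule,score
C5AR1,C10H9N5O,-35.3
C5AR1,v173,-30.1
C5AR1,v1024,-29
C5AR1,C17H15N3O6,-26.5
C5AR1,C20H12O5,-26.5
C5AR1,v461,-26.5
C5AR1,C8H10IN3,-25.9
C5AR1,C16H14N2O3,-25.8
C5AR1,C15H14N2O2,-25.7
C5AR1,v744,-25.5
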