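target,molecule,score
C4B,C21H18F3N3O5,-26.13
C4B,m,-24.36
C4B,C4H9N3O2,-21.65
C4B,C16H13Cl2,-21.51
C4B,v316,-21.45
C4B,C4H3N3O4,-21.21
C4B,v487,-20.36
C4B,v787,-20.26
C4B,v668,-20.18
C4B,v2148,-20.13
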