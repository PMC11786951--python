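target,molecule,score
C9,v174,-33.2
C9,C13H11NO3,-32.7
C9,v5147,-31.2
C9,v634,-31.2
C9,C15H14N2O2,-29.2
C9,C13H10O3,-29.1
C9,v723,-28.7
C9,v316,-28.6
C9,C11H6ClN3O6,-28.3
C9,v233,-28.1
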