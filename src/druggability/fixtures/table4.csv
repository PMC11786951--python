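target,molecule,score
DRD2,C20H15F3N4O3,-24.0
DRD2,C23H22ClN5O3,-23.94
DRD2,v629,-20.87
DRD2,v242,-20.3
DRD2,v763,-20.28
DRD2,v451,-20.15
DRD2,v1099,-20.1
DRD2,C20H17F3N2O4,-20.01
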