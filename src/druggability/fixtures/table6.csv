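target,molecule,score
GABA-A R,v555,-29.3
GABA-A R,C16H10N2O8S2,-26.8
GABA-A R,CH6O7P2,-26.4
GABA-A R,C21H19ClN4O4,-25.3
GABA-A R,C6H11KO7,-23.8
GABA-A R,C17H15ClO4,-23.7
GABA-A R,v963,-23.1
GABA-A R,C18H15NO8S2,-22.8
GABA-A R,v1165,-22.8
GABA-A R,C12H22MnO14,-22.3
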