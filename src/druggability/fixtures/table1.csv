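target,n_pockets,largest_volume,highest_hydrophobicity,buriedness,n_druggable
C1R,17,386.7,0.682,0.995,0
C3,37,1024,0.88,0.993,6
C1S,11,1761,0.586,0.824,1
C4B,27,879.1,0.7595,0.9128,5
C4A,4,295.1,0.631,0.859,0
CFH,8,467.5,0.566,0.778,0
SERPING1,3,259.5,0.575,0.803,0
C2A,9,334.9,0.63,0.82,0
C2B,2,393.5,0.568,0.87,0
C5AR1,5,348.8,0.771,0.865,0
RAB7,23,1368,0.593,0.884,5
BACE1,2,428.8,0.623,0.833,0
RAB11,4,387.9,0.529,0.805,0
ARF6,3,278.4,0.544,0.834,0
GABA-A R,62,1923,0.893,0.998,9
OPRD1,13,452.4,0.685,0.917,0
VTN,4,779.5,0.728,0.954,1
C1QB,10,542.9,0.595,0.983,1
C6,16,715.4,0.626,0.87,0
CLU,24,1035,0.885,0.949,0
C5,108,1686,0.838,0.98,11
C4BPA,11,250.3,0.693,0.816,0
CD59,0,,,,0
C9,23,614.1,0.895,0.996,5
DRD2,8,620.8,0.832,0.882,2
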