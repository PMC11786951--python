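target,dscore,site_score,volume,balance
C1R,1.235,1.134,332.367,6.057
DRD2,1.213,1.103,167.384,12.82
OPRD1,1.176,1.096,1353.135,3.447
C4BPA,1.093,1.016,343,1.479
C9,1.079,1.048,270.284,0.91
C5AR1,1.078,1.032,228.095,5.406
GABA-A R,1.065,1.035,2247.679,0.759
C4A,1.061,1.015,370.44,0.906
C4B,1.056,1.015,673.309,0.708
SERPING1,1.053,1.005,286.748,0.7
CLU,1.052,1.007,294.98,0.732
C6,1.038,0.994,822.857,0.473
C3,1.02,1.034,439.726,0.294
C1QB,1.011,1.126,479.171,0.549
RAB7,0.917,0.987,531.65,0.0005
CFH,0.888,0.903,248.332,0.119
RAB11,0.88,0.881,164.983,0.435
C2B,0.812,0.907,230.839,0.08
C1S,0.738,0.947,98.441,0.223
VTN,0.738,0.821,146.118,0.165
BACE1,0.735,0.806,244.559,0.034
C2A,0.656,0.778,200.655,0.081
ARF6,0.564,0.756,86.093,0.087
CD59,0.384,0.51,45.276,0.021
C5,,,,
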