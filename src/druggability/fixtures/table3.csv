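target,dlid_norm,spider_norm,sitemap_norm,composite
ARF6,0,0.75,0,0.750
C4BPA,0.113,0.5,0.788,1.401
C2B,0.178,0.5,0.370,1.047
CFH,0.196,0,0.483,0.679
C2A,0.198,0.5,0.137,0.835
SERPING1,0.213,0.5,0.729,1.442
RAB11,0.234,0.5,0.471,1.205
BACE1,0.277,0.75,0.255,1.282
CLU,0.302,0.75,0.727,1.779
OPRD1,0.317,0.5,0.912,1.729
C5AR1,0.373,0.75,0.766,1.889
C4A,0.396,0.75,0.741,1.887
C6,0.432,0.25,0.706,1.388
C1R,0.512,1,1,2.512
VTN,0.585,1,0.259,1.844
RAB7,0.651,0.5,0.526,1.677
C3,0.705,0.75,0.680,2.135
DRD2,0.746,0.75,0.967,2.464
C1QB,0.783,0.75,0.666,2.199
GABA-A R,0.896,0.75,0.747,2.393
C1S,0.931,0.5,0.259,1.690
C4B,0.959,0.75,0.733,2.442
C9,1,0.25,0.768,2.018
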