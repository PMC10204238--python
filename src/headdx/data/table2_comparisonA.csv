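,MO,MA,PM,CM,iETTH,fETTH,PTTH,CTTH,CH,NDPH,MOH,NEURALGIA,OTHERS
MO,115,0,0,0,0,0,0,0,0,0,1,0,0
MA,3,32,1,0,0,0,0,0,1,0,0,1,0
PM,11,0,77,0,0,0,0,1,0,0,0,2,0
CM,0,0,0,10,0,0,0,1,0,0,0,0,0
iETTH,0,0,0,0,11,0,0,0,0,0,0,0,0
fETTH,0,0,0,0,0,36,0,0,0,0,0,2,0
PTTH,0,0,0,0,0,8,53,0,0,0,0,7,0
CTTH,0,0,0,0,0,0,1,23,0,0,0,0,0
CH,0,0,0,0,0,0,0,0,8,0,0,2,0
NDPH,0,0,0,0,0,0,0,0,0,5,0,0,0
MOH,0,0,0,0,0,0,0,0,0,0,28,0,0
NEURALGIA,0,0,0,0,0,0,0,0,0,0,0,26,0
OTHERS,0,0,17,0,0,1,6,0,0,0,0,5,36
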