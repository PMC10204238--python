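,MO,MA,PM,CM,iETTH,fETTH,PTTH,CTTH,CH,NDPH,MOH,NEURALGIA,OTHERS
MO,111,0,1,0,0,0,3,0,0,0,0,1,0
MA,8,25,1,1,0,1,0,0,0,0,1,0,1
PM,18,0,64,0,0,0,1,0,2,0,2,4,0
CM,0,0,0,9,0,0,0,0,0,0,1,1,0
iETTH,0,1,2,0,8,0,0,0,0,0,0,0,0
fETTH,0,0,3,0,0,32,0,0,0,0,0,3,0
PTTH,0,0,8,0,1,3,47,1,0,0,0,8,0
CTTH,1,0,0,0,0,0,0,22,0,1,0,0,0
CH,0,0,3,0,0,0,0,0,7,0,0,0,0
NDPH,0,0,0,0,0,0,1,0,0,4,0,0,0
MOH,0,0,0,0,0,0,0,0,0,0,28,0,0
NEURALGIA,0,0,1,0,0,0,0,0,0,0,0,24,1
OTHERS,8,0,2,0,0,8,7,0,0,0,1,9,30
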