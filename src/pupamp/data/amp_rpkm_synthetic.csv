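transcript,L1,L2,L3,P0,P12,P24,P48,P96
drs,4,6,14,2600,900,260,40,12
drsl2,2,3,8,1110,420,120,18,6
drsl5,1,2,6,1325,510,140,22,7
drsl1,0,1,2,26,12,6,2,1
drsl3,1,1,3,24,11,5,2,1
drsl4,0,0,1,22,10,5,2,1
drsl6,0,0,1,21,9,4,1,0
AttA,2,3,5,20,9,4,2,1
AttB,1,2,4,19,8,4,1,1
AttC,1,1,3,18,8,3,1,0
AttD,0,1,2,17,7,3,1,0
CecA1,2,2,4,16,7,3,1,1
CecA2,1,1,3,15,6,3,1,0
CecB,0,1,2,14,6,2,1,0
CecC,0,0,1,13,5,2,1,0
Def,1,1,2,11,5,2,1,0
DptA,1,1,2,10,4,2,1,0
DptB,0,1,1,8,3,1,0,0
Dro,1,1,2,6,3,1,0,0
Mtk,1,1,2,5,2,1,0,0
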