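fossil_id,adult,L2,L3,L4,L5,combined
Kebara 2,True,8.1,6.9,4.5,-10.6,8.9
Shanidar 3,True,8.0,5.1,0.1,-4.9,8.3
La Chapelle-aux-Saints 1,True,,4.7,0.0,-7.8,
KNM-WT 15000,False,,,-8.3,-11.8,
LES1,True,3.0,,,,
SK 3981b,True,,,,-3.5,
MH2,True,4.1,1.4,-1.6,-11.2,-7.3
Sts 14,True,2.3,1.7,-0.9,-6.9,-3.8
StW 431,True,2.0,2.3,0.9,-4.2,1.1
StW 8,True,5.2,3.6,,,
StW 572,True,4.8,,,,
StW 656/600,True,,4.2,,-6.2,
A.L. 288-1,True,,7.2,,,
A.L. 333-73,True,,2.8,,,
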