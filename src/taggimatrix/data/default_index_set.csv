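label,role,spacer,index,group
A,forward,,GGTAC,1
B,forward,c,AACAC,1
C,forward,at,CGGTT,1
D,forward,tcg,GTCAA,1
E,forward,,AAGCG,2
F,forward,g,CCACA,2
G,forward,ct,GGATG,2
H,forward,tga,TTGAC,2
1,reverse,,AGGAA,3
2,reverse,g,AGTGG,3
3,reverse,cc,ACGTC,3
4,reverse,ttc,TCAGC,3
5,reverse,,CTAGG,4
6,reverse,t,GCTTA,4
7,reverse,gc,GAAGT,4
8,reverse,aat,CCTAT,4
9,reverse,,ATCTG,5
10,reverse,g,AGACT,5
11,reverse,cg,ATTCC,5
12,reverse,tct,CAATC,5
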