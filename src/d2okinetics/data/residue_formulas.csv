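residue,C,H,N,O,S,exchangeable_H
G,2,3,1,1,0,2.06
A,3,5,1,1,0,4.00
S,3,5,1,2,0,2.61
P,5,7,1,1,0,2.59
V,5,9,1,1,0,0.56
T,4,7,1,2,0,0.20
C,3,5,1,1,1,1.62
L,6,11,1,1,0,0.60
I,6,11,1,1,0,1.00
N,4,6,2,2,0,1.89
D,4,5,1,3,0,1.89
Q,5,8,2,2,0,3.95
K,6,12,2,1,0,0.54
E,5,7,1,3,0,3.95
M,5,9,1,1,1,1.12
H,6,7,3,1,0,2.88
F,9,9,1,1,0,0.32
R,6,12,4,1,0,3.43
Y,9,9,1,2,0,0.42
W,11,10,2,1,0,0.08
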