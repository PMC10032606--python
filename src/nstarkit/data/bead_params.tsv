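# nstarkit bead parameter table v1
# sc_sigma: side-chain vdW diameter (A) derived from standard residue volumes
# charge: side-chain charge (e) at neutral pH; bb_sc_bond: CA-SC bond length (A)
# sha256: 8aef142df01e8cbf854650b4b2cd3d747d8f0d979774d03bb6c7efb3c3050a3d
res sc_sigma charge bb_sc_bond
A 5.00 +0 1.50
C 5.50 +0 2.10
D 5.60 -1 2.50
E 6.00 -1 3.10
F 6.40 +0 3.40
G 4.50 +0 1.00
H 6.10 +0 3.20
I 6.20 +0 2.30
K 6.40 +1 3.50
L 6.20 +0 2.60
M 6.20 +0 2.90
N 5.70 +0 2.50
P 5.60 +0 1.90
Q 6.00 +0 3.10
R 6.60 +1 4.10
S 5.20 +0 1.90
T 5.60 +0 1.90
V 5.90 +0 2.00
W 6.80 +0 3.90
Y 6.50 +0 3.80
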