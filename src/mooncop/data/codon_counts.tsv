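residue	codons
A	4
C	2
D	2
E	2
F	2
G	4
H	2
I	3
K	2
L	6
M	1
N	2
P	4
Q	2
R	6
S	6
T	4
V	4
W	1
Y	2
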