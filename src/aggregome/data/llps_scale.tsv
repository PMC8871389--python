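residue	value
A	0.00
C	-0.40
D	0.15
E	0.20
F	0.60
G	0.70
H	0.30
I	-0.60
K	0.10
L	-0.60
M	-0.20
N	0.50
P	0.40
Q	0.50
R	0.80
S	0.40
T	0.10
V	-0.50
W	0.40
Y	0.90
X	0.00
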