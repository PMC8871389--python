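residue	value
A	0.30
C	0.50
D	-0.90
E	-0.90
F	0.75
G	0.00
H	-0.10
I	0.90
K	-1.00
L	0.80
M	0.40
N	-0.35
P	-0.80
Q	-0.35
R	-1.00
S	-0.05
T	0.00
V	0.85
W	0.45
Y	0.25
X	0.00
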