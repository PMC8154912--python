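# Isoelectric point of the free amino acid (CRC Handbook values),
# as used by Haig & Hurst (1991). Units: pH.
A	6.00
C	5.07
D	2.77
E	3.22
F	5.48
G	5.97
H	7.59
I	6.02
K	9.74
L	5.98
M	5.74
N	5.41
P	6.30
Q	5.65
R	10.76
S	5.68
T	5.60
V	5.96
W	5.89
Y	5.66
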