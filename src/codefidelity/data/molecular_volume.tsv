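# Molecular volume (Grantham 1974, Science 185:862-864),
# as used by Haig & Hurst (1991). Units: A^3.
A	31
C	55
D	54
E	83
F	132
G	3
H	96
I	111
K	119
L	111
M	105
N	56
P	32.5
Q	85
R	124
S	32
T	61
V	84
W	170
Y	136
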