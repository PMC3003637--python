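# Average residue masses (Da) for the 20 standard amino acids, plus the
# water mass added per peptide and the proton mass used for m/z.
A	71.0780
C	103.1428
D	115.0876
E	129.1142
F	147.1742
G	57.0514
H	137.1395
I	113.1579
K	128.1725
L	113.1579
M	131.1960
N	114.1028
P	97.1154
Q	128.1294
R	156.1859
S	87.0774
T	101.1040
V	99.1313
W	186.2103
Y	163.1736
water	18.0153
proton	1.00728
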