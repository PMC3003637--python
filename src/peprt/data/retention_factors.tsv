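# residue	k
F	6.435061
I	3.322726
L	3.989573
M	1.302959
V	1.085507
W	9.666333
Y	3.576216
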