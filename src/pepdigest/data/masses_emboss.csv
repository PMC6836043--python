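residue,average_mass,monoisotopic_mass
A,71.0779,71.03711
C,103.1429,103.00919
D,115.0874,115.02694
E,129.1140,129.04259
F,147.1739,147.06841
G,57.0513,57.02146
H,137.1393,137.05891
I,113.1576,113.08406
K,128.1723,128.09496
L,113.1576,113.08406
M,131.1961,131.04049
N,114.1026,114.04293
P,97.1152,97.05276
Q,128.1292,128.05858
R,156.1857,156.10111
S,87.0773,87.03203
T,101.1039,101.04768
V,99.1311,99.06841
W,186.2099,186.07931
Y,163.1733,163.06333
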