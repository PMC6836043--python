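group,pka
n_term,8.60
c_term,3.60
D,3.90
E,4.10
H,6.50
C,8.50
Y,10.10
K,10.80
R,12.50
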