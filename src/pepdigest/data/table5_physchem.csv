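sequence,molecular_weight,isoelectric_point,net_charge,solubility,bioactivity_score
AF,236.27,3.77,0,-,0.97
NR,288.30,10.42,1,+,0.26
AL,202.25,3.70,0,-,0.44
NY,295.29,3.24,0,-,0.22
AW,275.30,3.66,0,-,0.97
PL,228.29,4.08,0,-,0.81
AY,252.27,3.66,0,-,0.35
PF,262.30,4.15,0,-,0.99
DG,190.15,0.68,-1,+,0.39
PK,243.30,10.57,1,+,0.33
DR,289.29,6.68,0,+,0.29
PW,301.34,4.04,0,-,0.99
EK,275.30,6.85,0,+,0.02
PY,278.30,3.85,0,-,0.74
EW,333.34,0.88,-1,+,0.59
SF,252.27,3.43,0,-,0.95
EY,310.30,0.95,-1,+,0.07
SK,233.27,9.86,1,+,0.07
GF,222.24,3.70,0,-,0.99
SL,218.25,3.37,0,-,0.33
GL,188.22,3.63,0,-,0.81
SY,268.27,3.39,0,-,0.26
GY,238.24,3.61,0,-,0.74
SW,219.30,3.34,0,-,0.93
HF,302.33,7.56,0,-,0.95
TF,266.29,3.36,0,-,0.83
HL,268.31,7.56,0.1,-,0.37
TK,247.29,9.28,1,+,0.03
HR,311.34,10.59,1.1,+,0.33
TL,232.28,3.32,0,-,0.14
HW,341.36,7.56,0.1,-,0.95
TR,275.31,10.53,1,+,0.13
HY,318.33,7.54,0.1,-,0.30
TY,282.29,3.35,0,-,0.11
IL,244.33,3.64,0,-,0.39
QF,293.32,3.41,0,-,0.95
IR,287.36,10.85,1,+,0.33
QL,259.30,3.34,0,-,0.29
IW,317.38,3.61,0,-,0.94
QY,309.32,3.36,0,-,0.23
MF,296.39,3.45,0,-,1.00
VF,264.32,3.67,0,-,0.82
MK,277.39,9.88,1,+,0.45
VK,245.32,10.10,1,+,0.03
ML,262.37,3.38,0,-,0.89
VL,230.30,3.60,0,-,0.13
MR,305.40,10.59,1,+,0.85
VR,273.33,10.10,1,+,0.11
MW,335.42,3.35,0,-,1.00
VW,303.36,3.57,0,-,0.80
NF,279.29,3.28,0,-,0.94
VY,280.32,3.59,0,-,0.10
NL,245.28,3.21,0,-,0.29
VPL,327.42,3.60,0,-,0.37
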