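sequence,activity_class,ec50,ec50_unit,source
AF,dpp4_inhibitor,,,released-set reference
NR,dpp4_inhibitor,,,released-set reference
AL,dpp4_inhibitor,,,released-set reference
NY,dpp4_inhibitor,,,released-set reference
AW,dpp4_inhibitor,,,released-set reference
PL,dpp4_inhibitor,,,released-set reference
AY,dpp4_inhibitor,,,released-set reference
PF,dpp4_inhibitor,,,released-set reference
DG,dpp4_inhibitor,,,released-set reference
PK,dpp4_inhibitor,,,released-set reference
DR,dpp4_inhibitor,,,released-set reference
PW,dpp4_inhibitor,,,released-set reference
EK,dpp4_inhibitor,,,released-set reference
PY,dpp4_inhibitor,,,released-set reference
EW,dpp4_inhibitor,,,released-set reference
SF,dpp4_inhibitor,,,released-set reference
EY,dpp4_inhibitor,,,released-set reference
SK,dpp4_inhibitor,,,released-set reference
GF,dpp4_inhibitor,,,released-set reference
SL,dpp4_inhibitor,,,released-set reference
GL,dpp4_inhibitor,,,released-set reference
SY,dpp4_inhibitor,,,released-set reference
GY,dpp4_inhibitor,,,released-set reference
SW,dpp4_inhibitor,,,released-set reference
HF,dpp4_inhibitor,,,released-set reference
TF,dpp4_inhibitor,,,released-set reference
HL,dpp4_inhibitor,,,released-set reference
TK,dpp4_inhibitor,,,released-set reference
HR,dpp4_inhibitor,,,released-set reference
TL,dpp4_inhibitor,,,released-set reference
HW,dpp4_inhibitor,,,released-set reference
TR,dpp4_inhibitor,,,released-set reference
HY,dpp4_inhibitor,,,released-set reference
TY,dpp4_inhibitor,,,released-set reference
IL,dpp4_inhibitor,,,released-set reference
QF,dpp4_inhibitor,,,released-set reference
IR,dpp4_inhibitor,,,released-set reference
QL,dpp4_inhibitor,,,released-set reference
IW,dpp4_inhibitor,,,released-set reference
QY,dpp4_inhibitor,,,released-set reference
MF,dpp4_inhibitor,,,released-set reference
VF,dpp4_inhibitor,,,released-set reference
MK,dpp4_inhibitor,,,released-set reference
VK,dpp4_inhibitor,,,released-set reference
ML,dpp4_inhibitor,,,released-set reference
VL,dpp4_inhibitor,,,released-set reference
MR,dpp4_inhibitor,,,released-set reference
VR,dpp4_inhibitor,,,released-set reference
MW,dpp4_inhibitor,,,released-set reference
VW,dpp4_inhibitor,,,released-set reference
NF,dpp4_inhibitor,,,released-set reference
VY,dpp4_inhibitor,,,released-set reference
NL,dpp4_inhibitor,,,released-set reference
VPL,dpp4_inhibitor,,,released-set reference
IL,gusp,,,released-set reference
VL,gusp,,,released-set reference
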