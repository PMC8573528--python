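label,theta_deg,phi_deg
Fp1,90,108
AF7,90,126
AF3,72.3913,115
F1,48.913,112
F3,58.6957,129
F5,73.3696,139
F7,90,144
FT7,90,162
FC5,70.4348,159
FC3,48.913,152
FC1,31.3043,135
C1,22.5,180
C3,45,180
C5,67.5,180
T7,90,180
TP7,90,-162
CP5,70.4348,-159
CP3,48.913,-152
CP1,31.3043,-135
P1,48.913,-112
P3,58.6957,-129
P5,73.3696,-139
P7,90,-144
P9,112.5,-144
PO7,90,-126
PO3,72.3913,-115
O1,90,-108
Iz,112.5,-90
Oz,90,-90
POz,67.5,-90
Pz,45,-90
CPz,22.5,-90
FPz,90,90
Fp2,90,72
AF8,90,54
AF4,72.3913,65
AFz,67.5,90
Fz,45,90
F2,48.913,68
F4,58.6957,51
F6,73.3696,41
F8,90,36
FT8,90,18
FC6,70.4348,21
FC4,48.913,28
FC2,31.3043,45
FCz,22.5,90
Cz,0,0
C2,22.5,0
C4,45,0
C6,67.5,0
T8,90,0
TP8,90,-18
CP6,70.4348,-21
CP4,48.913,-28
CP2,31.3043,-45
P2,48.913,-68
P4,58.6957,-51
P6,73.3696,-41
P8,90,-36
P10,112.5,-36
PO8,90,-54
PO4,72.3913,-65
O2,90,-72
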