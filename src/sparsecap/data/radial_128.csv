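label,theta_deg,phi_deg
Cz,0,0
A2,10.7609,-90
A3,22.5,-90
A4,33.2609,-90
A5,45,-113
A6,45,-135
A7,55.7609,-135
A8,67.5,-126
A9,78.2609,-126
A10,90,-126
A11,100.761,-126
A12,112.5,-126
A13,112.5,-108
A14,100.761,-108
A15,90,-108
A16,78.2609,-108
A17,67.5,-108
A18,55.7609,-113
A19,45,-90
A20,55.7609,-90
A21,67.5,-90
A22,78.2609,-90
Oz,90,-90
A24,100.761,-90
A25,112.5,-90
A26,112.5,-72
A27,100.761,-72
A28,90,-72
A29,78.2609,-72
A30,67.5,-72
A31,55.7609,-67
A32,45,-67
B1,10.7609,-18
B2,22.5,-45
B3,45,-45
B4,55.7609,-45
B5,67.5,-54
B6,78.2609,-54
B7,90,-54
B8,100.761,-54
B9,112.5,-54
B10,100.761,-36
B11,90,-36
B12,78.2609,-36
B13,67.5,-36
B14,90,-18
B15,78.2609,-18
B16,67.5,-18
B17,55.7609,-22
B18,45,-22
B19,33.2609,-30
B20,22.5,0
B21,33.2609,0
B22,45,0
B23,55.7609,0
B24,67.5,0
B25,78.2609,0
T8,90,0
B27,90,18
B28,78.2609,18
B29,67.5,18
B30,55.7609,22
B31,45,22
B32,33.2609,30
C1,10.7609,54
C2,22.5,45
C3,45,45
C4,55.7609,45
C5,67.5,36
C6,78.2609,36
C7,90,36
C8,90,54
C9,78.2609,54
C10,67.5,54
C11,33.2609,60
C12,45,67
C13,55.7609,67
C14,67.5,72
C15,78.2609,72
C16,90,72
FPz,90,90
C18,78.2609,90
C19,67.5,90
C20,55.7609,90
C21,45,90
C22,33.2609,90
C23,22.5,90
C24,33.2609,120
C25,45,113
C26,55.7609,113
C27,67.5,108
C28,78.2609,108
C29,90,108
C30,90,126
C31,78.2609,126
C32,67.5,126
D1,10.7609,126
D2,22.5,135
D3,45,135
D4,55.7609,135
D5,67.5,144
D6,78.2609,144
D7,90,144
D8,90,162
D9,78.2609,162
D10,67.5,162
D11,55.7609,158
D12,45,158
D13,33.2609,150
D14,22.5,180
D15,10.7609,-162
D16,22.5,-135
D17,33.2609,-150
D18,33.2609,180
D19,45,180
D20,55.7609,180
D21,67.5,180
D22,78.2609,180
T7,90,180
D24,90,-162
D25,78.2609,-162
D26,67.5,-162
D27,55.7609,-158
D28,45,-158
D29,67.5,-144
D30,78.2609,-144
D31,90,-144
D32,100.761,-144
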