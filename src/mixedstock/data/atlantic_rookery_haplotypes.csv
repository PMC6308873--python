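population,CM-A1,CM-A3,CM-A4,CM-A5,CM-A6,CM-A8,CM-A9,CM-A10,CM-A12,CM-A50
MT,4,5,0,21,0,8,1,0,0,1
AV,0,3,0,27,0,0,0,0,0,0
GD,0,1,0,35,0,0,0,0,0,0
SU,0,0,0,31,0,1,0,0,0,0
FGc,0,0,0,17,1,2,0,1,1,0
FGa,0,0,1,21,0,0,0,0,0,0
CB,3,16,0,0,0,0,0,0,0,0
FL,11,12,0,0,0,0,0,0,0,0
MX,7,5,0,1,0,0,0,0,0,0
CR,0,95,0,32,0,0,0,0,0,0
RA,0,0,0,0,0,36,7,0,0,0
TI,0,0,0,0,0,67,19,0,0,0
GB,0,0,0,0,0,70,0,0,0,0
AI,0,0,0,0,0,204,9,0,0,1
BI,0,0,0,0,0,45,0,0,0,0
ST,0,0,0,1,0,13,0,0,0,0
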