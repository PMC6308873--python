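population,region
AV,Eastern Caribbean
GD,Eastern Caribbean
SU,Eastern Caribbean
FGc,Eastern Caribbean
FGa,Eastern Caribbean
CB,Northern Western Caribbean
FL,Northern Western Caribbean
MX,Northern Western Caribbean
CR,Northern Western Caribbean
RA,Southwest Atlantic
TI,Southwest Atlantic
GB,Southeast Atlantic
AI,Southeast Atlantic
BI,Southeast Atlantic
ST,Southeast Atlantic
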