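res_name,reference_sasa_A2
ALA,112.996
ARG,241.11
ASN,160.908
ASP,158.965
CYS,143.276
GLN,191.156
GLU,190.295
GLY,87.42
HIS,188.951
ILE,175.313
LEU,181.57
LYS,207.787
MET,199.503
PHE,214.467
PRO,133.75
SER,130.012
THR,143.344
TRP,256.228
TYR,231.088
VAL,148.756
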