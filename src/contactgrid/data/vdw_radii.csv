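residue,atom,element,radius
ALA,N,N,1.55
ALA,CA,C,1.70
ALA,C,C,1.70
ALA,O,O,1.52
ALA,CB,C,1.70
ALA,OXT,O,1.52
ARG,N,N,1.55
ARG,CA,C,1.70
ARG,C,C,1.70
ARG,O,O,1.52
ARG,CB,C,1.70
ARG,CG,C,1.70
ARG,CD,C,1.70
ARG,NE,N,1.55
ARG,CZ,C,1.70
ARG,NH1,N,1.55
ARG,NH2,N,1.55
ARG,OXT,O,1.52
ASN,N,N,1.55
ASN,CA,C,1.70
ASN,C,C,1.70
ASN,O,O,1.52
ASN,CB,C,1.70
ASN,CG,C,1.70
ASN,OD1,O,1.52
ASN,ND2,N,1.55
ASN,OXT,O,1.52
ASP,N,N,1.55
ASP,CA,C,1.70
ASP,C,C,1.70
ASP,O,O,1.52
ASP,CB,C,1.70
ASP,CG,C,1.70
ASP,OD1,O,1.52
ASP,OD2,O,1.52
ASP,OXT,O,1.52
CYS,N,N,1.55
CYS,CA,C,1.70
CYS,C,C,1.70
CYS,O,O,1.52
CYS,CB,C,1.70
CYS,SG,S,1.80
CYS,OXT,O,1.52
GLN,N,N,1.55
GLN,CA,C,1.70
GLN,C,C,1.70
GLN,O,O,1.52
GLN,CB,C,1.70
GLN,CG,C,1.70
GLN,CD,C,1.70
GLN,OE1,O,1.52
GLN,NE2,N,1.55
GLN,OXT,O,1.52
GLU,N,N,1.55
GLU,CA,C,1.70
GLU,C,C,1.70
GLU,O,O,1.52
GLU,CB,C,1.70
GLU,CG,C,1.70
GLU,CD,C,1.70
GLU,OE1,O,1.52
GLU,OE2,O,1.52
GLU,OXT,O,1.52
GLY,N,N,1.55
GLY,CA,C,1.70
GLY,C,C,1.70
GLY,O,O,1.52
GLY,OXT,O,1.52
HIS,N,N,1.55
HIS,CA,C,1.70
HIS,C,C,1.70
HIS,O,O,1.52
HIS,CB,C,1.70
HIS,CG,C,1.70
HIS,ND1,N,1.55
HIS,CD2,C,1.70
HIS,CE1,C,1.70
HIS,NE2,N,1.55
HIS,OXT,O,1.52
ILE,N,N,1.55
ILE,CA,C,1.70
ILE,C,C,1.70
ILE,O,O,1.52
ILE,CB,C,1.70
ILE,CG1,C,1.70
ILE,CG2,C,1.70
ILE,CD1,C,1.70
ILE,OXT,O,1.52
LEU,N,N,1.55
LEU,CA,C,1.70
LEU,C,C,1.70
LEU,O,O,1.52
LEU,CB,C,1.70
LEU,CG,C,1.70
LEU,CD1,C,1.70
LEU,CD2,C,1.70
LEU,OXT,O,1.52
LYS,N,N,1.55
LYS,CA,C,1.70
LYS,C,C,1.70
LYS,O,O,1.52
LYS,CB,C,1.70
LYS,CG,C,1.70
LYS,CD,C,1.70
LYS,CE,C,1.70
LYS,NZ,N,1.55
LYS,OXT,O,1.52
MET,N,N,1.55
MET,CA,C,1.70
MET,C,C,1.70
MET,O,O,1.52
MET,CB,C,1.70
MET,CG,C,1.70
MET,SD,S,1.80
MET,CE,C,1.70
MET,OXT,O,1.52
PHE,N,N,1.55
PHE,CA,C,1.70
PHE,C,C,1.70
PHE,O,O,1.52
PHE,CB,C,1.70
PHE,CG,C,1.70
PHE,CD1,C,1.70
PHE,CD2,C,1.70
PHE,CE1,C,1.70
PHE,CE2,C,1.70
PHE,CZ,C,1.70
PHE,OXT,O,1.52
PRO,N,N,1.55
PRO,CA,C,1.70
PRO,C,C,1.70
PRO,O,O,1.52
PRO,CB,C,1.70
PRO,CG,C,1.70
PRO,CD,C,1.70
PRO,OXT,O,1.52
SER,N,N,1.55
SER,CA,C,1.70
SER,C,C,1.70
SER,O,O,1.52
SER,CB,C,1.70
SER,OG,O,1.52
SER,OXT,O,1.52
THR,N,N,1.55
THR,CA,C,1.70
THR,C,C,1.70
THR,O,O,1.52
THR,CB,C,1.70
THR,OG1,O,1.52
THR,CG2,C,1.70
THR,OXT,O,1.52
TRP,N,N,1.55
TRP,CA,C,1.70
TRP,C,C,1.70
TRP,O,O,1.52
TRP,CB,C,1.70
TRP,CG,C,1.70
TRP,CD1,C,1.70
TRP,CD2,C,1.70
TRP,NE1,N,1.55
TRP,CE2,C,1.70
TRP,CE3,C,1.70
TRP,CZ2,C,1.70
TRP,CZ3,C,1.70
TRP,CH2,C,1.70
TRP,OXT,O,1.52
TYR,N,N,1.55
TYR,CA,C,1.70
TYR,C,C,1.70
TYR,O,O,1.52
TYR,CB,C,1.70
TYR,CG,C,1.70
TYR,CD1,C,1.70
TYR,CD2,C,1.70
TYR,CE1,C,1.70
TYR,CE2,C,1.70
TYR,CZ,C,1.70
TYR,OH,O,1.52
TYR,OXT,O,1.52
VAL,N,N,1.55
VAL,CA,C,1.70
VAL,C,C,1.70
VAL,O,O,1.52
VAL,CB,C,1.70
VAL,CG1,C,1.70
VAL,CG2,C,1.70
VAL,OXT,O,1.52
HOH,O,O,1.52
WAT,O,O,1.52
*,B,B,1.92
*,BR,BR,1.85
*,C,C,1.70
*,CA,CA,2.31
*,CL,CL,1.75
*,CU,CU,1.40
*,F,F,1.47
*,FE,FE,2.00
*,I,I,1.98
*,K,K,2.75
*,MG,MG,1.73
*,MN,MN,2.00
*,N,N,1.55
*,NA,NA,2.27
*,O,O,1.52
*,P,P,1.80
*,S,S,1.80
*,SE,SE,1.90
*,ZN,ZN,1.39
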