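residue,atom,donor,acceptor,aromatic
ALA,N,1,0,0
ALA,CA,0,0,0
ALA,C,0,0,0
ALA,O,0,1,0
ALA,CB,0,0,0
ALA,OXT,0,1,0
ARG,N,1,0,0
ARG,CA,0,0,0
ARG,C,0,0,0
ARG,O,0,1,0
ARG,CB,0,0,0
ARG,CG,0,0,0
ARG,CD,0,0,0
ARG,NE,1,0,0
ARG,CZ,0,0,0
ARG,NH1,1,0,0
ARG,NH2,1,0,0
ARG,OXT,0,1,0
ASN,N,1,0,0
ASN,CA,0,0,0
ASN,C,0,0,0
ASN,O,0,1,0
ASN,CB,0,0,0
ASN,CG,0,0,0
ASN,OD1,0,1,0
ASN,ND2,1,0,0
ASN,OXT,0,1,0
ASP,N,1,0,0
ASP,CA,0,0,0
ASP,C,0,0,0
ASP,O,0,1,0
ASP,CB,0,0,0
ASP,CG,0,0,0
ASP,OD1,0,1,0
ASP,OD2,0,1,0
ASP,OXT,0,1,0
CYS,N,1,0,0
CYS,CA,0,0,0
CYS,C,0,0,0
CYS,O,0,1,0
CYS,CB,0,0,0
CYS,SG,1,1,0
CYS,OXT,0,1,0
GLN,N,1,0,0
GLN,CA,0,0,0
GLN,C,0,0,0
GLN,O,0,1,0
GLN,CB,0,0,0
GLN,CG,0,0,0
GLN,CD,0,0,0
GLN,OE1,0,1,0
GLN,NE2,1,0,0
GLN,OXT,0,1,0
GLU,N,1,0,0
GLU,CA,0,0,0
GLU,C,0,0,0
GLU,O,0,1,0
GLU,CB,0,0,0
GLU,CG,0,0,0
GLU,CD,0,0,0
GLU,OE1,0,1,0
GLU,OE2,0,1,0
GLU,OXT,0,1,0
GLY,N,1,0,0
GLY,CA,0,0,0
GLY,C,0,0,0
GLY,O,0,1,0
GLY,OXT,0,1,0
HIS,N,1,0,0
HIS,CA,0,0,0
HIS,C,0,0,0
HIS,O,0,1,0
HIS,CB,0,0,0
HIS,CG,0,0,1
HIS,ND1,1,1,0
HIS,CD2,0,0,1
HIS,CE1,0,0,1
HIS,NE2,1,1,0
HIS,OXT,0,1,0
ILE,N,1,0,0
ILE,CA,0,0,0
ILE,C,0,0,0
ILE,O,0,1,0
ILE,CB,0,0,0
ILE,CG1,0,0,0
ILE,CG2,0,0,0
ILE,CD1,0,0,0
ILE,OXT,0,1,0
LEU,N,1,0,0
LEU,CA,0,0,0
LEU,C,0,0,0
LEU,O,0,1,0
LEU,CB,0,0,0
LEU,CG,0,0,0
LEU,CD1,0,0,0
LEU,CD2,0,0,0
LEU,OXT,0,1,0
LYS,N,1,0,0
LYS,CA,0,0,0
LYS,C,0,0,0
LYS,O,0,1,0
LYS,CB,0,0,0
LYS,CG,0,0,0
LYS,CD,0,0,0
LYS,CE,0,0,0
LYS,NZ,1,0,0
LYS,OXT,0,1,0
MET,N,1,0,0
MET,CA,0,0,0
MET,C,0,0,0
MET,O,0,1,0
MET,CB,0,0,0
MET,CG,0,0,0
MET,SD,0,1,0
MET,CE,0,0,0
MET,OXT,0,1,0
PHE,N,1,0,0
PHE,CA,0,0,0
PHE,C,0,0,0
PHE,O,0,1,0
PHE,CB,0,0,0
PHE,CG,0,0,1
PHE,CD1,0,0,1
PHE,CD2,0,0,1
PHE,CE1,0,0,1
PHE,CE2,0,0,1
PHE,CZ,0,0,1
PHE,OXT,0,1,0
PRO,N,0,0,0
PRO,CA,0,0,0
PRO,C,0,0,0
PRO,O,0,1,0
PRO,CB,0,0,0
PRO,CG,0,0,0
PRO,CD,0,0,0
PRO,OXT,0,1,0
SER,N,1,0,0
SER,CA,0,0,0
SER,C,0,0,0
SER,O,0,1,0
SER,CB,0,0,0
SER,OG,1,1,0
SER,OXT,0,1,0
THR,N,1,0,0
THR,CA,0,0,0
THR,C,0,0,0
THR,O,0,1,0
THR,CB,0,0,0
THR,OG1,1,1,0
THR,CG2,0,0,0
THR,OXT,0,1,0
TRP,N,1,0,0
TRP,CA,0,0,0
TRP,C,0,0,0
TRP,O,0,1,0
TRP,CB,0,0,0
TRP,CG,0,0,1
TRP,CD1,0,0,1
TRP,CD2,0,0,1
TRP,NE1,1,0,1
TRP,CE2,0,0,1
TRP,CE3,0,0,1
TRP,CZ2,0,0,1
TRP,CZ3,0,0,1
TRP,CH2,0,0,1
TRP,OXT,0,1,0
TYR,N,1,0,0
TYR,CA,0,0,0
TYR,C,0,0,0
TYR,O,0,1,0
TYR,CB,0,0,0
TYR,CG,0,0,1
TYR,CD1,0,0,1
TYR,CD2,0,0,1
TYR,CE1,0,0,1
TYR,CE2,0,0,1
TYR,CZ,0,0,1
TYR,OH,1,1,0
TYR,OXT,0,1,0
VAL,N,1,0,0
VAL,CA,0,0,0
VAL,C,0,0,0
VAL,O,0,1,0
VAL,CB,0,0,0
VAL,CG1,0,0,0
VAL,CG2,0,0,0
VAL,OXT,0,1,0
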