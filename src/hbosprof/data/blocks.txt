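# Distal-block atom names per residue type: the outermost rigid atom group
# of the sidechain.  One line per type: RES_TYPE followed by atom names.
# Editable config: corrections to the block partition require no code change.
ARG NE CZ NH1 NH2
ASN CG OD1 ND2
ASP CG OD1 OD2
CYS SG
GLN CD OE1 NE2
GLU CD OE1 OE2
HIS CG ND1 CD2 CE1 NE2
ILE CG1 CD1
LEU CG CD1 CD2
LYS CE NZ
MET SD CE
PHE CG CD1 CD2 CE1 CE2 CZ
PRO CB CG CD
SER OG
THR CB OG1 CG2
TRP CG CD1 CD2 NE1 CE2 CE3 CZ2 CZ3 CH2
TYR CG CD1 CD2 CE1 CE2 CZ OH
VAL CB CG1 CG2
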