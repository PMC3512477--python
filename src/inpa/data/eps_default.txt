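# Default per-residue relative dielectric constants.
# A deliberately flat table (eps = 4 for every standard amino acid):
# residue-specific polarizability-derived values may be supplied by the
# user as a file in the same two-column format.
ALA 4.0
ARG 4.0
ASN 4.0
ASP 4.0
CYS 4.0
GLN 4.0
GLU 4.0
GLY 4.0
HIS 4.0
ILE 4.0
LEU 4.0
LYS 4.0
MET 4.0
PHE 4.0
PRO 4.0
SER 4.0
THR 4.0
TRP 4.0
TYR 4.0
VAL 4.0
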