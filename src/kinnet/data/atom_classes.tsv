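# LPC-style atom classification, reconstructed from the published
# 8-class scheme (hydrophilic, hydrophobic, aromatic, acceptor,
# donor, neutral, neutral-donor, neutral-acceptor).
# residue '*' rows are element-keyed fallbacks for HET groups.
res_type	atom	class
ALA	N	donor
ALA	CA	neutral
ALA	C	neutral
ALA	O	acceptor
ALA	OXT	acceptor
ALA	CB	hydrophobic
ALA	CB2	hydrophobic
ARG	N	donor
ARG	CA	neutral
ARG	C	neutral
ARG	O	acceptor
ARG	OXT	acceptor
ARG	CB	hydrophobic
ARG	CG	hydrophobic
ARG	CD	neutral
ARG	NE	donor
ARG	CZ	neutral
ARG	NH1	donor
ARG	NH2	donor
ARG	CB2	hydrophobic
ASN	N	donor
ASN	CA	neutral
ASN	C	neutral
ASN	O	acceptor
ASN	OXT	acceptor
ASN	CB	hydrophobic
ASN	CG	neutral
ASN	OD1	acceptor
ASN	ND2	donor
ASN	CB2	hydrophobic
ASP	N	donor
ASP	CA	neutral
ASP	C	neutral
ASP	O	acceptor
ASP	OXT	acceptor
ASP	CB	hydrophobic
ASP	CG	neutral
ASP	OD1	acceptor
ASP	OD2	acceptor
ASP	CB2	hydrophobic
CYS	N	donor
CYS	CA	neutral
CYS	C	neutral
CYS	O	acceptor
CYS	OXT	acceptor
CYS	CB	hydrophobic
CYS	SG	hydrophilic
CYS	CB2	hydrophobic
GLN	N	donor
GLN	CA	neutral
GLN	C	neutral
GLN	O	acceptor
GLN	OXT	acceptor
GLN	CB	hydrophobic
GLN	CG	hydrophobic
GLN	CD	neutral
GLN	OE1	acceptor
GLN	NE2	donor
GLN	CB2	hydrophobic
GLU	N	donor
GLU	CA	neutral
GLU	C	neutral
GLU	O	acceptor
GLU	OXT	acceptor
GLU	CB	hydrophobic
GLU	CG	hydrophobic
GLU	CD	neutral
GLU	OE1	acceptor
GLU	OE2	acceptor
GLU	CB2	hydrophobic
GLY	N	donor
GLY	CA	neutral
GLY	C	neutral
GLY	O	acceptor
GLY	OXT	acceptor
GLY	CB2	hydrophobic
HIS	N	donor
HIS	CA	neutral
HIS	C	neutral
HIS	O	acceptor
HIS	OXT	acceptor
HIS	CB	hydrophobic
HIS	CG	aromatic
HIS	ND1	neutral-donor
HIS	CD2	aromatic
HIS	CE1	aromatic
HIS	NE2	neutral-acceptor
HIS	CB2	hydrophobic
ILE	N	donor
ILE	CA	neutral
ILE	C	neutral
ILE	O	acceptor
ILE	OXT	acceptor
ILE	CB	hydrophobic
ILE	CG1	hydrophobic
ILE	CG2	hydrophobic
ILE	CD1	hydrophobic
ILE	CB2	hydrophobic
LEU	N	donor
LEU	CA	neutral
LEU	C	neutral
LEU	O	acceptor
LEU	OXT	acceptor
LEU	CB	hydrophobic
LEU	CG	hydrophobic
LEU	CD1	hydrophobic
LEU	CD2	hydrophobic
LEU	CB2	hydrophobic
LYS	N	donor
LYS	CA	neutral
LYS	C	neutral
LYS	O	acceptor
LYS	OXT	acceptor
LYS	CB	hydrophobic
LYS	CG	hydrophobic
LYS	CD	hydrophobic
LYS	CE	neutral
LYS	NZ	donor
LYS	CB2	hydrophobic
MET	N	donor
MET	CA	neutral
MET	C	neutral
MET	O	acceptor
MET	OXT	acceptor
MET	CB	hydrophobic
MET	CG	hydrophobic
MET	SD	neutral
MET	CE	hydrophobic
MET	CB2	hydrophobic
PHE	N	donor
PHE	CA	neutral
PHE	C	neutral
PHE	O	acceptor
PHE	OXT	acceptor
PHE	CB	hydrophobic
PHE	CG	aromatic
PHE	CD1	aromatic
PHE	CD2	aromatic
PHE	CE1	aromatic
PHE	CE2	aromatic
PHE	CZ	aromatic
PHE	CB2	hydrophobic
PRO	N	neutral
PRO	CA	neutral
PRO	C	neutral
PRO	O	acceptor
PRO	OXT	acceptor
PRO	CB	hydrophobic
PRO	CG	hydrophobic
PRO	CD	neutral
PRO	CB2	hydrophobic
SER	N	donor
SER	CA	neutral
SER	C	neutral
SER	O	acceptor
SER	OXT	acceptor
SER	CB	neutral
SER	OG	hydrophilic
SER	CB2	hydrophobic
THR	N	donor
THR	CA	neutral
THR	C	neutral
THR	O	acceptor
THR	OXT	acceptor
THR	CB	neutral
THR	OG1	hydrophilic
THR	CG2	hydrophobic
THR	CB2	hydrophobic
TRP	N	donor
TRP	CA	neutral
TRP	C	neutral
TRP	O	acceptor
TRP	OXT	acceptor
TRP	CB	hydrophobic
TRP	CG	aromatic
TRP	CD1	aromatic
TRP	CD2	aromatic
TRP	NE1	donor
TRP	CE2	aromatic
TRP	CE3	aromatic
TRP	CZ2	aromatic
TRP	CZ3	aromatic
TRP	CH2	aromatic
TRP	CB2	hydrophobic
TYR	N	donor
TYR	CA	neutral
TYR	C	neutral
TYR	O	acceptor
TYR	OXT	acceptor
TYR	CB	hydrophobic
TYR	CG	aromatic
TYR	CD1	aromatic
TYR	CD2	aromatic
TYR	CE1	aromatic
TYR	CE2	aromatic
TYR	CZ	aromatic
TYR	OH	hydrophilic
TYR	CB2	hydrophobic
VAL	N	donor
VAL	CA	neutral
VAL	C	neutral
VAL	O	acceptor
VAL	OXT	acceptor
VAL	CB	hydrophobic
VAL	CG1	hydrophobic
VAL	CG2	hydrophobic
VAL	CB2	hydrophobic
*	C	hydrophobic
*	N	donor
*	O	acceptor
*	S	neutral
*	P	neutral
*	F	hydrophobic
*	CL	hydrophobic
*	BR	hydrophobic
*	I	hydrophobic
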