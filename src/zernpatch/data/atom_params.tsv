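# zernpatch atom parameter table v1
# radius: Å; charge: e (approximate, point-charge scale); logp: Crippen-style atomic contribution; hbond_class in {donor, acceptor, dual, none}
residue	atom	radius	charge	logp	hbond_class
ALA	N	1.55	-0.40	-0.60	donor
ALA	CA	1.70	0.05	0.36	none
ALA	C	1.70	0.55	-0.20	none
ALA	O	1.52	-0.55	-0.40	acceptor
ALA	OXT	1.52	-0.80	-0.40	acceptor
ALA	CB	1.70	0.00	0.36	none
ARG	N	1.55	-0.40	-0.60	donor
ARG	CA	1.70	0.05	0.36	none
ARG	C	1.70	0.55	-0.20	none
ARG	O	1.52	-0.55	-0.40	acceptor
ARG	OXT	1.52	-0.80	-0.40	acceptor
ARG	CB	1.70	0.00	0.36	none
ARG	CG	1.70	0.00	0.36	none
ARG	CD	1.70	0.00	0.36	none
ARG	NE	1.55	-0.50	-0.60	donor
ARG	CZ	1.70	0.60	-0.20	none
ARG	NH1	1.55	0.45	-0.60	donor
ARG	NH2	1.55	0.45	-0.60	donor
ASN	N	1.55	-0.40	-0.60	donor
ASN	CA	1.70	0.05	0.36	none
ASN	C	1.70	0.55	-0.20	none
ASN	O	1.52	-0.55	-0.40	acceptor
ASN	OXT	1.52	-0.80	-0.40	acceptor
ASN	CB	1.70	0.00	0.36	none
ASN	CG	1.70	0.55	-0.20	none
ASN	OD1	1.52	-0.55	-0.40	acceptor
ASN	ND2	1.55	-0.60	-0.60	donor
ASP	N	1.55	-0.40	-0.60	donor
ASP	CA	1.70	0.05	0.36	none
ASP	C	1.70	0.55	-0.20	none
ASP	O	1.52	-0.55	-0.40	acceptor
ASP	OXT	1.52	-0.80	-0.40	acceptor
ASP	CB	1.70	0.00	0.36	none
ASP	CG	1.70	0.70	-0.20	none
ASP	OD1	1.52	-0.80	-0.40	acceptor
ASP	OD2	1.52	-0.80	-0.40	acceptor
CYS	N	1.55	-0.40	-0.60	donor
CYS	CA	1.70	0.05	0.36	none
CYS	C	1.70	0.55	-0.20	none
CYS	O	1.52	-0.55	-0.40	acceptor
CYS	OXT	1.52	-0.80	-0.40	acceptor
CYS	CB	1.70	0.00	0.36	none
CYS	SG	1.80	-0.25	0.45	donor
GLN	N	1.55	-0.40	-0.60	donor
GLN	CA	1.70	0.05	0.36	none
GLN	C	1.70	0.55	-0.20	none
GLN	O	1.52	-0.55	-0.40	acceptor
GLN	OXT	1.52	-0.80	-0.40	acceptor
GLN	CB	1.70	0.00	0.36	none
GLN	CG	1.70	0.00	0.36	none
GLN	CD	1.70	0.55	-0.20	none
GLN	OE1	1.52	-0.55	-0.40	acceptor
GLN	NE2	1.55	-0.60	-0.60	donor
GLU	N	1.55	-0.40	-0.60	donor
GLU	CA	1.70	0.05	0.36	none
GLU	C	1.70	0.55	-0.20	none
GLU	O	1.52	-0.55	-0.40	acceptor
GLU	OXT	1.52	-0.80	-0.40	acceptor
GLU	CB	1.70	0.00	0.36	none
GLU	CG	1.70	0.00	0.36	none
GLU	CD	1.70	0.70	-0.20	none
GLU	OE1	1.52	-0.80	-0.40	acceptor
GLU	OE2	1.52	-0.80	-0.40	acceptor
GLY	N	1.55	-0.40	-0.60	donor
GLY	CA	1.70	0.05	0.36	none
GLY	C	1.70	0.55	-0.20	none
GLY	O	1.52	-0.55	-0.40	acceptor
GLY	OXT	1.52	-0.80	-0.40	acceptor
HIS	N	1.55	-0.40	-0.60	donor
HIS	CA	1.70	0.05	0.36	none
HIS	C	1.70	0.55	-0.20	none
HIS	O	1.52	-0.55	-0.40	acceptor
HIS	OXT	1.52	-0.80	-0.40	acceptor
HIS	CB	1.70	0.00	0.36	none
HIS	CG	1.70	0.00	0.29	none
HIS	ND1	1.55	-0.35	-0.60	dual
HIS	CD2	1.70	0.00	0.29	none
HIS	CE1	1.70	0.00	0.29	none
HIS	NE2	1.55	-0.35	-0.60	dual
ILE	N	1.55	-0.40	-0.60	donor
ILE	CA	1.70	0.05	0.36	none
ILE	C	1.70	0.55	-0.20	none
ILE	O	1.52	-0.55	-0.40	acceptor
ILE	OXT	1.52	-0.80	-0.40	acceptor
ILE	CB	1.70	0.00	0.36	none
ILE	CG1	1.70	0.00	0.36	none
ILE	CG2	1.70	0.00	0.36	none
ILE	CD1	1.70	0.00	0.36	none
LEU	N	1.55	-0.40	-0.60	donor
LEU	CA	1.70	0.05	0.36	none
LEU	C	1.70	0.55	-0.20	none
LEU	O	1.52	-0.55	-0.40	acceptor
LEU	OXT	1.52	-0.80	-0.40	acceptor
LEU	CB	1.70	0.00	0.36	none
LEU	CG	1.70	0.00	0.36	none
LEU	CD1	1.70	0.00	0.36	none
LEU	CD2	1.70	0.00	0.36	none
LYS	N	1.55	-0.40	-0.60	donor
LYS	CA	1.70	0.05	0.36	none
LYS	C	1.70	0.55	-0.20	none
LYS	O	1.52	-0.55	-0.40	acceptor
LYS	OXT	1.52	-0.80	-0.40	acceptor
LYS	CB	1.70	0.00	0.36	none
LYS	CG	1.70	0.00	0.36	none
LYS	CD	1.70	0.00	0.36	none
LYS	CE	1.70	0.20	0.36	none
LYS	NZ	1.55	0.80	-0.60	donor
MET	N	1.55	-0.40	-0.60	donor
MET	CA	1.70	0.05	0.36	none
MET	C	1.70	0.55	-0.20	none
MET	O	1.52	-0.55	-0.40	acceptor
MET	OXT	1.52	-0.80	-0.40	acceptor
MET	CB	1.70	0.00	0.36	none
MET	CG	1.70	0.00	0.36	none
MET	SD	1.80	-0.10	0.45	acceptor
MET	CE	1.70	0.00	0.36	none
PHE	N	1.55	-0.40	-0.60	donor
PHE	CA	1.70	0.05	0.36	none
PHE	C	1.70	0.55	-0.20	none
PHE	O	1.52	-0.55	-0.40	acceptor
PHE	OXT	1.52	-0.80	-0.40	acceptor
PHE	CB	1.70	0.00	0.36	none
PHE	CG	1.70	0.00	0.29	none
PHE	CD1	1.70	0.00	0.29	none
PHE	CD2	1.70	0.00	0.29	none
PHE	CE1	1.70	0.00	0.29	none
PHE	CE2	1.70	0.00	0.29	none
PHE	CZ	1.70	0.00	0.29	none
PRO	N	1.55	-0.40	-0.60	none
PRO	CA	1.70	0.05	0.36	none
PRO	C	1.70	0.55	-0.20	none
PRO	O	1.52	-0.55	-0.40	acceptor
PRO	OXT	1.52	-0.80	-0.40	acceptor
PRO	CB	1.70	0.00	0.36	none
PRO	CG	1.70	0.00	0.36	none
PRO	CD	1.70	0.00	0.36	none
SER	N	1.55	-0.40	-0.60	donor
SER	CA	1.70	0.05	0.36	none
SER	C	1.70	0.55	-0.20	none
SER	O	1.52	-0.55	-0.40	acceptor
SER	OXT	1.52	-0.80	-0.40	acceptor
SER	CB	1.70	0.00	0.36	none
SER	OG	1.52	-0.55	-0.40	dual
THR	N	1.55	-0.40	-0.60	donor
THR	CA	1.70	0.05	0.36	none
THR	C	1.70	0.55	-0.20	none
THR	O	1.52	-0.55	-0.40	acceptor
THR	OXT	1.52	-0.80	-0.40	acceptor
THR	CB	1.70	0.00	0.36	none
THR	OG1	1.52	-0.55	-0.40	dual
THR	CG2	1.70	0.00	0.36	none
TRP	N	1.55	-0.40	-0.60	donor
TRP	CA	1.70	0.05	0.36	none
TRP	C	1.70	0.55	-0.20	none
TRP	O	1.52	-0.55	-0.40	acceptor
TRP	OXT	1.52	-0.80	-0.40	acceptor
TRP	CB	1.70	0.00	0.36	none
TRP	CG	1.70	0.00	0.29	none
TRP	CD1	1.70	0.00	0.29	none
TRP	CD2	1.70	0.00	0.29	none
TRP	NE1	1.55	-0.35	-0.60	donor
TRP	CE2	1.70	0.00	0.29	none
TRP	CE3	1.70	0.00	0.29	none
TRP	CZ2	1.70	0.00	0.29	none
TRP	CZ3	1.70	0.00	0.29	none
TRP	CH2	1.70	0.00	0.29	none
TYR	N	1.55	-0.40	-0.60	donor
TYR	CA	1.70	0.05	0.36	none
TYR	C	1.70	0.55	-0.20	none
TYR	O	1.52	-0.55	-0.40	acceptor
TYR	OXT	1.52	-0.80	-0.40	acceptor
TYR	CB	1.70	0.00	0.36	none
TYR	CG	1.70	0.00	0.29	none
TYR	CD1	1.70	0.00	0.29	none
TYR	CD2	1.70	0.00	0.29	none
TYR	CE1	1.70	0.00	0.29	none
TYR	CE2	1.70	0.00	0.29	none
TYR	CZ	1.70	0.00	0.29	none
TYR	OH	1.52	-0.50	-0.40	dual
VAL	N	1.55	-0.40	-0.60	donor
VAL	CA	1.70	0.05	0.36	none
VAL	C	1.70	0.55	-0.20	none
VAL	O	1.52	-0.55	-0.40	acceptor
VAL	OXT	1.52	-0.80	-0.40	acceptor
VAL	CB	1.70	0.00	0.36	none
VAL	CG1	1.70	0.00	0.36	none
VAL	CG2	1.70	0.00	0.36	none
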