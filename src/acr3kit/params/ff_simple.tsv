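# acr3kit simplified force-field table, version 1
residue	atom	charge	lj_epsilon	lj_rmin	gb_radius	vdw_radius
ALA	N	-0.300	0.170	1.824	1.550	1.550
ALA	CA	0.100	0.109	1.908	1.700	1.700
ALA	C	0.450	0.086	1.908	1.700	1.700
ALA	O	-0.450	0.210	1.661	1.500	1.520
ALA	CB	0.200	0.100	1.900	1.900	1.900
ARG	N	-0.300	0.170	1.824	1.550	1.550
ARG	CA	0.100	0.109	1.908	1.700	1.700
ARG	C	0.450	0.086	1.908	1.700	1.700
ARG	O	-0.450	0.210	1.661	1.500	1.520
ARG	CB	1.200	0.100	2.800	2.800	2.800
ASN	N	-0.300	0.170	1.824	1.550	1.550
ASN	CA	0.100	0.109	1.908	1.700	1.700
ASN	C	0.450	0.086	1.908	1.700	1.700
ASN	O	-0.450	0.210	1.661	1.500	1.520
ASN	CB	0.200	0.100	2.200	2.200	2.200
ASP	N	-0.300	0.170	1.824	1.550	1.550
ASP	CA	0.100	0.109	1.908	1.700	1.700
ASP	C	0.450	0.086	1.908	1.700	1.700
ASP	O	-0.450	0.210	1.661	1.500	1.520
ASP	CB	-0.800	0.100	2.200	2.200	2.200
CYS	N	-0.300	0.170	1.824	1.550	1.550
CYS	CA	0.100	0.109	1.908	1.700	1.700
CYS	C	0.450	0.086	1.908	1.700	1.700
CYS	O	-0.450	0.210	1.661	1.500	1.520
CYS	CB	0.200	0.100	2.000	2.000	2.000
GLN	N	-0.300	0.170	1.824	1.550	1.550
GLN	CA	0.100	0.109	1.908	1.700	1.700
GLN	C	0.450	0.086	1.908	1.700	1.700
GLN	O	-0.450	0.210	1.661	1.500	1.520
GLN	CB	0.200	0.100	2.400	2.400	2.400
GLU	N	-0.300	0.170	1.824	1.550	1.550
GLU	CA	0.100	0.109	1.908	1.700	1.700
GLU	C	0.450	0.086	1.908	1.700	1.700
GLU	O	-0.450	0.210	1.661	1.500	1.520
GLU	CB	-0.800	0.100	2.400	2.400	2.400
GLY	N	-0.300	0.170	1.824	1.550	1.550
GLY	CA	0.300	0.109	1.908	1.700	1.700
GLY	C	0.450	0.086	1.908	1.700	1.700
GLY	O	-0.450	0.210	1.661	1.500	1.520
HIS	N	-0.300	0.170	1.824	1.550	1.550
HIS	CA	0.100	0.109	1.908	1.700	1.700
HIS	C	0.450	0.086	1.908	1.700	1.700
HIS	O	-0.450	0.210	1.661	1.500	1.520
HIS	CB	0.200	0.100	2.500	2.500	2.500
ILE	N	-0.300	0.170	1.824	1.550	1.550
ILE	CA	0.100	0.109	1.908	1.700	1.700
ILE	C	0.450	0.086	1.908	1.700	1.700
ILE	O	-0.450	0.210	1.661	1.500	1.520
ILE	CB	0.200	0.100	2.400	2.400	2.400
LEU	N	-0.300	0.170	1.824	1.550	1.550
LEU	CA	0.100	0.109	1.908	1.700	1.700
LEU	C	0.450	0.086	1.908	1.700	1.700
LEU	O	-0.450	0.210	1.661	1.500	1.520
LEU	CB	0.200	0.100	2.400	2.400	2.400
LYS	N	-0.300	0.170	1.824	1.550	1.550
LYS	CA	0.100	0.109	1.908	1.700	1.700
LYS	C	0.450	0.086	1.908	1.700	1.700
LYS	O	-0.450	0.210	1.661	1.500	1.520
LYS	CB	1.200	0.100	2.600	2.600	2.600
MET	N	-0.300	0.170	1.824	1.550	1.550
MET	CA	0.100	0.109	1.908	1.700	1.700
MET	C	0.450	0.086	1.908	1.700	1.700
MET	O	-0.450	0.210	1.661	1.500	1.520
MET	CB	0.200	0.100	2.500	2.500	2.500
PHE	N	-0.300	0.170	1.824	1.550	1.550
PHE	CA	0.100	0.109	1.908	1.700	1.700
PHE	C	0.450	0.086	1.908	1.700	1.700
PHE	O	-0.450	0.210	1.661	1.500	1.520
PHE	CB	0.200	0.100	2.600	2.600	2.600
PRO	N	-0.300	0.170	1.824	1.550	1.550
PRO	CA	0.100	0.109	1.908	1.700	1.700
PRO	C	0.450	0.086	1.908	1.700	1.700
PRO	O	-0.450	0.210	1.661	1.500	1.520
PRO	CB	0.200	0.100	2.100	2.100	2.100
SER	N	-0.300	0.170	1.824	1.550	1.550
SER	CA	0.100	0.109	1.908	1.700	1.700
SER	C	0.450	0.086	1.908	1.700	1.700
SER	O	-0.450	0.210	1.661	1.500	1.520
SER	CB	0.200	0.100	1.900	1.900	1.900
THR	N	-0.300	0.170	1.824	1.550	1.550
THR	CA	0.100	0.109	1.908	1.700	1.700
THR	C	0.450	0.086	1.908	1.700	1.700
THR	O	-0.450	0.210	1.661	1.500	1.520
THR	CB	0.200	0.100	2.100	2.100	2.100
TRP	N	-0.300	0.170	1.824	1.550	1.550
TRP	CA	0.100	0.109	1.908	1.700	1.700
TRP	C	0.450	0.086	1.908	1.700	1.700
TRP	O	-0.450	0.210	1.661	1.500	1.520
TRP	CB	0.200	0.100	2.900	2.900	2.900
TYR	N	-0.300	0.170	1.824	1.550	1.550
TYR	CA	0.100	0.109	1.908	1.700	1.700
TYR	C	0.450	0.086	1.908	1.700	1.700
TYR	O	-0.450	0.210	1.661	1.500	1.520
TYR	CB	0.200	0.100	2.700	2.700	2.700
VAL	N	-0.300	0.170	1.824	1.550	1.550
VAL	CA	0.100	0.109	1.908	1.700	1.700
VAL	C	0.450	0.086	1.908	1.700	1.700
VAL	O	-0.450	0.210	1.661	1.500	1.520
VAL	CB	0.200	0.100	2.200	2.200	2.200
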