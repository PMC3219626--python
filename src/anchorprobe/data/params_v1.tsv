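# anchorprobe united-atom parameter table, version 1
# residue	atom	element	class	charge_e	eps_kcal	sigma_A	radius_A	asp_cal_molA2	polar
ALA	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
ALA	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
ALA	C	C	C	0.380	0.105	3.75	1.90	16.0	1
ALA	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
ALA	CB	C	CH3	0.000	0.170	3.75	2.00	16.0	0
ALA	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
ARG	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
ARG	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
ARG	C	C	C	0.380	0.105	3.75	1.90	16.0	1
ARG	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
ARG	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
ARG	CG	C	CH2	0.000	0.118	3.90	2.00	16.0	0
ARG	CD	C	CH2	0.090	0.118	3.90	2.00	16.0	0
ARG	NE	N	NC	-0.110	0.170	3.25	1.65	-24.0	1
ARG	CZ	C	C	0.420	0.105	3.75	1.90	16.0	1
ARG	NH1	N	NC	0.300	0.170	3.25	1.65	-50.0	1
ARG	NH2	N	NC	0.300	0.170	3.25	1.65	-50.0	1
ARG	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
ASN	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
ASN	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
ASN	C	C	C	0.380	0.105	3.75	1.90	16.0	1
ASN	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
ASN	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
ASN	CG	C	C	0.380	0.105	3.75	1.90	16.0	1
ASN	OD1	O	O	-0.380	0.210	2.96	1.50	-6.0	1
ASN	ND2	N	N	0.000	0.170	3.25	1.65	-6.0	1
ASN	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
ASP	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
ASP	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
ASP	C	C	C	0.380	0.105	3.75	1.90	16.0	1
ASP	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
ASP	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
ASP	CG	C	C	0.270	0.105	3.75	1.90	16.0	0
ASP	OD1	O	OM	-0.635	0.210	2.96	1.50	-24.0	1
ASP	OD2	O	OM	-0.635	0.210	2.96	1.50	-24.0	1
ASP	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
CYS	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
CYS	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
CYS	C	C	C	0.380	0.105	3.75	1.90	16.0	1
CYS	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
CYS	CB	C	CH2	0.100	0.118	3.90	2.00	16.0	0
CYS	SG	S	S	-0.100	0.250	3.55	1.85	21.0	1
CYS	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
GLN	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
GLN	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
GLN	C	C	C	0.380	0.105	3.75	1.90	16.0	1
GLN	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
GLN	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
GLN	CG	C	CH2	0.000	0.118	3.90	2.00	16.0	0
GLN	CD	C	C	0.380	0.105	3.75	1.90	16.0	1
GLN	OE1	O	O	-0.380	0.210	2.96	1.50	-6.0	1
GLN	NE2	N	N	0.000	0.170	3.25	1.65	-6.0	1
GLN	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
GLU	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
GLU	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
GLU	C	C	C	0.380	0.105	3.75	1.90	16.0	1
GLU	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
GLU	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
GLU	CG	C	CH2	0.000	0.118	3.90	2.00	16.0	0
GLU	CD	C	C	0.270	0.105	3.75	1.90	16.0	0
GLU	OE1	O	OM	-0.635	0.210	2.96	1.50	-24.0	1
GLU	OE2	O	OM	-0.635	0.210	2.96	1.50	-24.0	1
GLU	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
GLY	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
GLY	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
GLY	C	C	C	0.380	0.105	3.75	1.90	16.0	1
GLY	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
GLY	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
HIS	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
HIS	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
HIS	C	C	C	0.380	0.105	3.75	1.90	16.0	1
HIS	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
HIS	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
HIS	CG	C	C	0.000	0.105	3.75	1.90	16.0	0
HIS	ND1	N	NR	-0.200	0.170	3.25	1.65	-6.0	1
HIS	CD2	C	CAr	0.000	0.110	3.70	1.85	16.0	0
HIS	CE1	C	CAr	0.200	0.110	3.70	1.85	16.0	0
HIS	NE2	N	NR	0.000	0.170	3.25	1.65	-6.0	1
HIS	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
ILE	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
ILE	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
ILE	C	C	C	0.380	0.105	3.75	1.90	16.0	1
ILE	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
ILE	CB	C	CH1	0.000	0.090	4.20	2.00	16.0	0
ILE	CG1	C	CH2	0.000	0.118	3.90	2.00	16.0	0
ILE	CG2	C	CH3	0.000	0.170	3.75	2.00	16.0	0
ILE	CD1	C	CH3	0.000	0.170	3.75	2.00	16.0	0
ILE	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
LEU	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
LEU	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
LEU	C	C	C	0.380	0.105	3.75	1.90	16.0	1
LEU	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
LEU	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
LEU	CG	C	CH1	0.000	0.090	4.20	2.00	16.0	0
LEU	CD1	C	CH3	0.000	0.170	3.75	2.00	16.0	0
LEU	CD2	C	CH3	0.000	0.170	3.75	2.00	16.0	0
LEU	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
LYS	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
LYS	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
LYS	C	C	C	0.380	0.105	3.75	1.90	16.0	1
LYS	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
LYS	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
LYS	CG	C	CH2	0.000	0.118	3.90	2.00	16.0	0
LYS	CD	C	CH2	0.000	0.118	3.90	2.00	16.0	0
LYS	CE	C	CH2	0.250	0.118	3.90	2.00	16.0	0
LYS	NZ	N	NC	0.750	0.170	3.25	1.65	-50.0	1
LYS	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
MET	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
MET	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
MET	C	C	C	0.380	0.105	3.75	1.90	16.0	1
MET	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
MET	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
MET	CG	C	CH2	0.000	0.118	3.90	2.00	16.0	0
MET	SD	S	S	0.000	0.250	3.55	1.85	21.0	1
MET	CE	C	CH3	0.000	0.170	3.75	2.00	16.0	0
MET	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
PHE	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
PHE	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
PHE	C	C	C	0.380	0.105	3.75	1.90	16.0	1
PHE	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
PHE	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
PHE	CG	C	C	0.000	0.105	3.75	1.90	16.0	0
PHE	CD1	C	CAr	0.000	0.110	3.70	1.85	16.0	0
PHE	CD2	C	CAr	0.000	0.110	3.70	1.85	16.0	0
PHE	CE1	C	CAr	0.000	0.110	3.70	1.85	16.0	0
PHE	CE2	C	CAr	0.000	0.110	3.70	1.85	16.0	0
PHE	CZ	C	CAr	0.000	0.110	3.70	1.85	16.0	0
PHE	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
PRO	N	N	N	-0.560	0.170	3.25	1.65	-6.0	1
PRO	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
PRO	C	C	C	0.380	0.105	3.75	1.90	16.0	1
PRO	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
PRO	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
PRO	CG	C	CH2	0.000	0.118	3.90	2.00	16.0	0
PRO	CD	C	CH2	0.280	0.118	3.90	2.00	16.0	0
PRO	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
SER	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
SER	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
SER	C	C	C	0.380	0.105	3.75	1.90	16.0	1
SER	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
SER	CB	C	CH2	0.200	0.118	3.90	2.00	16.0	0
SER	OG	O	OA	-0.200	0.210	3.00	1.50	-6.0	1
SER	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
THR	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
THR	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
THR	C	C	C	0.380	0.105	3.75	1.90	16.0	1
THR	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
THR	CB	C	CH1	0.200	0.090	4.20	2.00	16.0	0
THR	OG1	O	OA	-0.200	0.210	3.00	1.50	-6.0	1
THR	CG2	C	CH3	0.000	0.170	3.75	2.00	16.0	0
THR	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
TRP	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
TRP	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
TRP	C	C	C	0.380	0.105	3.75	1.90	16.0	1
TRP	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
TRP	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
TRP	CG	C	C	0.000	0.105	3.75	1.90	16.0	0
TRP	CD1	C	CAr	0.100	0.110	3.70	1.85	16.0	0
TRP	NE1	N	NR	-0.100	0.170	3.25	1.65	-6.0	1
TRP	CD2	C	C	0.000	0.105	3.75	1.90	16.0	0
TRP	CE2	C	C	0.000	0.105	3.75	1.90	16.0	0
TRP	CE3	C	CAr	0.000	0.110	3.70	1.85	16.0	0
TRP	CZ2	C	CAr	0.000	0.110	3.70	1.85	16.0	0
TRP	CZ3	C	CAr	0.000	0.110	3.70	1.85	16.0	0
TRP	CH2	C	CAr	0.000	0.110	3.70	1.85	16.0	0
TRP	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
TYR	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
TYR	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
TYR	C	C	C	0.380	0.105	3.75	1.90	16.0	1
TYR	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
TYR	CB	C	CH2	0.000	0.118	3.90	2.00	16.0	0
TYR	CG	C	C	0.000	0.105	3.75	1.90	16.0	0
TYR	CD1	C	CAr	0.000	0.110	3.70	1.85	16.0	0
TYR	CD2	C	CAr	0.000	0.110	3.70	1.85	16.0	0
TYR	CE1	C	CAr	0.000	0.110	3.70	1.85	16.0	0
TYR	CE2	C	CAr	0.000	0.110	3.70	1.85	16.0	0
TYR	CZ	C	C	0.200	0.105	3.75	1.90	16.0	0
TYR	OH	O	OA	-0.200	0.210	3.00	1.50	-6.0	1
TYR	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
VAL	N	N	N	-0.280	0.170	3.25	1.65	-6.0	1
VAL	CA	C	CH1	0.280	0.090	4.20	2.00	16.0	0
VAL	C	C	C	0.380	0.105	3.75	1.90	16.0	1
VAL	O	O	O	-0.380	0.210	2.96	1.50	-6.0	1
VAL	CB	C	CH1	0.000	0.090	4.20	2.00	16.0	0
VAL	CG1	C	CH3	0.000	0.170	3.75	2.00	16.0	0
VAL	CG2	C	CH3	0.000	0.170	3.75	2.00	16.0	0
VAL	OXT	O	OM	-0.380	0.210	2.96	1.50	-24.0	1
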