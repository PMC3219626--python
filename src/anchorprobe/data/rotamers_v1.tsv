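# anchorprobe backbone-independent rotamer library, version 1
# residue	chi1	chi2	chi3	chi4
ARG	-60	-60	-60	-60
ARG	-60	-60	-60	90
ARG	-60	-60	-60	180
ARG	-60	-60	180	-60
ARG	-60	-60	180	90
ARG	-60	-60	180	180
ARG	-60	180	-60	-60
ARG	-60	180	-60	90
ARG	-60	180	-60	180
ARG	-60	180	180	-60
ARG	-60	180	180	90
ARG	-60	180	180	180
ARG	180	-60	-60	-60
ARG	180	-60	-60	90
ARG	180	-60	-60	180
ARG	180	-60	180	-60
ARG	180	-60	180	90
ARG	180	-60	180	180
ARG	180	180	-60	-60
ARG	180	180	-60	90
ARG	180	180	-60	180
ARG	180	180	180	-60
ARG	180	180	180	90
ARG	180	180	180	180
ASN	-60	-30
ASN	-60	30
ASN	-60	90
ASN	180	-30
ASN	180	30
ASN	180	90
ASN	60	-30
ASN	60	30
ASN	60	90
ASP	-60	-30
ASP	-60	30
ASP	-60	90
ASP	180	-30
ASP	180	30
ASP	180	90
ASP	60	-30
ASP	60	30
ASP	60	90
CYS	-60
CYS	60
CYS	180
GLN	-60	-60	-30
GLN	-60	-60	30
GLN	-60	-60	90
GLN	-60	180	-30
GLN	-60	180	30
GLN	-60	180	90
GLN	-60	60	-30
GLN	-60	60	30
GLN	-60	60	90
GLN	180	-60	-30
GLN	180	-60	30
GLN	180	-60	90
GLN	180	180	-30
GLN	180	180	30
GLN	180	180	90
GLN	180	60	-30
GLN	180	60	30
GLN	180	60	90
GLN	60	-60	-30
GLN	60	-60	30
GLN	60	-60	90
GLN	60	180	-30
GLN	60	180	30
GLN	60	180	90
GLN	60	60	-30
GLN	60	60	30
GLN	60	60	90
GLU	-60	-60	-20
GLU	-60	-60	20
GLU	-60	-60	90
GLU	-60	180	-20
GLU	-60	180	20
GLU	-60	180	90
GLU	-60	60	-20
GLU	-60	60	20
GLU	-60	60	90
GLU	180	-60	-20
GLU	180	-60	20
GLU	180	-60	90
GLU	180	180	-20
GLU	180	180	20
GLU	180	180	90
GLU	180	60	-20
GLU	180	60	20
GLU	180	60	90
GLU	60	-60	-20
GLU	60	-60	20
GLU	60	-60	90
GLU	60	180	-20
GLU	60	180	20
GLU	60	180	90
GLU	60	60	-20
GLU	60	60	20
GLU	60	60	90
ILE	-60	170
ILE	-60	-60
ILE	180	165
ILE	60	170
LEU	-60	180
LEU	180	60
LEU	-60	60
LEU	180	180
LYS	-60	-60	-60	-60
LYS	-60	-60	-60	180
LYS	-60	-60	180	-60
LYS	-60	-60	180	180
LYS	-60	180	-60	-60
LYS	-60	180	-60	180
LYS	-60	180	180	-60
LYS	-60	180	180	180
LYS	180	-60	-60	-60
LYS	180	-60	-60	180
LYS	180	-60	180	-60
LYS	180	-60	180	180
LYS	180	180	-60	-60
LYS	180	180	-60	180
LYS	180	180	180	-60
LYS	180	180	180	180
MET	-60	180	-60
MET	-60	180	60
MET	-60	180	180
MET	-60	-60	-60
MET	-60	-60	60
MET	-60	-60	180
MET	-60	60	-60
MET	-60	60	60
MET	-60	60	180
MET	180	180	-60
MET	180	180	60
MET	180	180	180
MET	180	-60	-60
MET	180	-60	60
MET	180	-60	180
MET	180	60	-60
MET	180	60	60
MET	180	60	180
PHE	-60	90
PHE	-60	30
PHE	180	90
PHE	180	30
PHE	60	90
PHE	60	30
SER	-60
SER	60
SER	180
THR	-60
THR	60
THR	180
VAL	-60
VAL	60
VAL	180
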