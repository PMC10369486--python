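# Side-chain construction templates: each heavy atom is placed by NeRF from
# three reference atoms (bonded to ref3) with ideal bond length (A), bond
# angle (deg, at ref2-ref3-atom) and a torsion rule:
#   const   - fixed dihedral(ref1,ref2,ref3,atom) in degrees (tor_value)
#   chi     - dihedral equals sampled chi_k (tor_value = k)
#   chioff  - dihedral equals chi_k + offset (tor_value = "k+off" / "k-off")
#   prochi2 - PRO only: dihedral = tor_value * chi1 (open-ring pucker coupling)
# CB placement uses the improper dihedral N-C-CA-CB = -122.6 deg (L chirality).
aa	atom	ref1	ref2	ref3	length	angle	tor_type	tor_value
ALA	CB	N	C	CA	1.521	110.5	const	122.6
ARG	CB	N	C	CA	1.530	110.5	const	122.6
ARG	CG	N	CA	CB	1.520	114.1	chi	1
ARG	CD	CA	CB	CG	1.520	111.3	chi	2
ARG	NE	CB	CG	CD	1.461	112.0	chi	3
ARG	CZ	CG	CD	NE	1.329	124.2	chi	4
ARG	NH1	CD	NE	CZ	1.326	120.0	const	0
ARG	NH2	CD	NE	CZ	1.326	120.0	const	180
ASN	CB	N	C	CA	1.530	110.5	const	122.6
ASN	CG	N	CA	CB	1.516	112.6	chi	1
ASN	OD1	CA	CB	CG	1.231	120.8	chi	2
ASN	ND2	CA	CB	CG	1.328	116.4	chioff	2+180
ASP	CB	N	C	CA	1.530	110.5	const	122.6
ASP	CG	N	CA	CB	1.516	112.6	chi	1
ASP	OD1	CA	CB	CG	1.249	118.4	chi	2
ASP	OD2	CA	CB	CG	1.249	118.4	chioff	2+180
CYS	CB	N	C	CA	1.530	110.5	const	122.6
CYS	SG	N	CA	CB	1.808	114.4	chi	1
GLN	CB	N	C	CA	1.530	110.5	const	122.6
GLN	CG	N	CA	CB	1.520	114.1	chi	1
GLN	CD	CA	CB	CG	1.516	112.6	chi	2
GLN	OE1	CB	CG	CD	1.231	120.8	chi	3
GLN	NE2	CB	CG	CD	1.328	116.4	chioff	3+180
GLU	CB	N	C	CA	1.530	110.5	const	122.6
GLU	CG	N	CA	CB	1.520	114.1	chi	1
GLU	CD	CA	CB	CG	1.516	112.6	chi	2
GLU	OE1	CB	CG	CD	1.249	118.4	chi	3
GLU	OE2	CB	CG	CD	1.249	118.4	chioff	3+180
HIS	CB	N	C	CA	1.530	110.5	const	122.6
HIS	CG	N	CA	CB	1.497	113.8	chi	1
HIS	ND1	CA	CB	CG	1.378	122.7	chi	2
HIS	CD2	CA	CB	CG	1.354	131.0	chioff	2+180
HIS	CE1	CB	CG	ND1	1.321	109.0	const	180
HIS	NE2	CB	CG	CD2	1.374	107.0	const	180
ILE	CB	N	C	CA	1.540	110.5	const	122.6
ILE	CG1	N	CA	CB	1.530	110.4	chi	1
ILE	CG2	N	CA	CB	1.521	110.5	chioff	1-120
ILE	CD1	CA	CB	CG1	1.513	113.9	chi	2
LEU	CB	N	C	CA	1.530	110.5	const	122.6
LEU	CG	N	CA	CB	1.530	116.3	chi	1
LEU	CD1	CA	CB	CG	1.521	110.7	chi	2
LEU	CD2	CA	CB	CG	1.521	110.7	chioff	2+120
LYS	CB	N	C	CA	1.530	110.5	const	122.6
LYS	CG	N	CA	CB	1.520	114.1	chi	1
LYS	CD	CA	CB	CG	1.520	111.3	chi	2
LYS	CE	CB	CG	CD	1.520	111.3	chi	3
LYS	NZ	CG	CD	CE	1.489	111.9	chi	4
MET	CB	N	C	CA	1.530	110.5	const	122.6
MET	CG	N	CA	CB	1.520	114.1	chi	1
MET	SD	CA	CB	CG	1.803	112.7	chi	2
MET	CE	CB	CG	SD	1.791	100.9	chi	3
PHE	CB	N	C	CA	1.530	110.5	const	122.6
PHE	CG	N	CA	CB	1.502	113.8	chi	1
PHE	CD1	CA	CB	CG	1.384	120.8	chi	2
PHE	CD2	CA	CB	CG	1.384	120.8	chioff	2+180
PHE	CE1	CB	CG	CD1	1.382	120.8	const	180
PHE	CE2	CB	CG	CD2	1.382	120.8	const	180
PHE	CZ	CG	CD1	CE1	1.382	120.0	const	0
PRO	CB	N	C	CA	1.530	103.0	const	120.0
PRO	CG	N	CA	CB	1.492	104.5	chi	1
PRO	CD	CA	CB	CG	1.503	106.1	prochi2	-1.2
SER	CB	N	C	CA	1.530	110.5	const	122.6
SER	OG	N	CA	CB	1.417	110.8	chi	1
THR	CB	N	C	CA	1.540	110.5	const	122.6
THR	OG1	N	CA	CB	1.433	109.6	chi	1
THR	CG2	N	CA	CB	1.521	110.5	chioff	1-120
TRP	CB	N	C	CA	1.530	110.5	const	122.6
TRP	CG	N	CA	CB	1.498	113.6	chi	1
TRP	CD1	CA	CB	CG	1.365	127.0	chi	2
TRP	CD2	CA	CB	CG	1.433	126.6	chioff	2+180
TRP	NE1	CB	CG	CD1	1.374	110.2	const	180
TRP	CE2	CB	CG	CD2	1.409	107.2	const	180
TRP	CE3	CB	CG	CD2	1.398	133.9	const	0
TRP	CZ2	CG	CD2	CE2	1.394	122.4	const	180
TRP	CZ3	CG	CD2	CE3	1.392	118.7	const	180
TRP	CH2	CD2	CE2	CZ2	1.372	117.5	const	180
TYR	CB	N	C	CA	1.530	110.5	const	122.6
TYR	CG	N	CA	CB	1.512	113.9	chi	1
TYR	CD1	CA	CB	CG	1.389	120.8	chi	2
TYR	CD2	CA	CB	CG	1.389	120.8	chioff	2+180
TYR	CE1	CB	CG	CD1	1.382	121.1	const	180
TYR	CE2	CB	CG	CD2	1.382	121.1	const	180
TYR	CZ	CG	CD1	CE1	1.378	119.6	const	0
TYR	OH	CD1	CE1	CZ	1.376	119.9	const	180
VAL	CB	N	C	CA	1.540	110.5	const	122.6
VAL	CG1	N	CA	CB	1.521	110.5	chi	1
VAL	CG2	N	CA	CB	1.521	110.5	chioff	1+120
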