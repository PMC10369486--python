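# Canonical rotamer class inventory (per-chi mode vectors, degrees).
# PRO uses chi1 only (ring pucker: Cγ Endo +30, Cγ Exo -30).
aa	label	mode1	mode2	mode3	mode4
ARG	mmm-85°	-65	-65	-65	-85
ARG	mmm180°	-65	-65	-65	180
ARG	mmt-85°	-65	-65	180	-85
ARG	mmt180°	-65	-65	180	180
ARG	mmt85°	-65	-65	180	85
ARG	mtm-85°	-65	180	-65	-85
ARG	mtm105°	-65	180	-65	105
ARG	mtm180°	-65	180	-65	180
ARG	mtp-105°	-65	180	65	-105
ARG	mtp180°	-65	180	65	180
ARG	mtp85°	-65	180	65	85
ARG	mtt-85°	-65	180	180	-85
ARG	mtt180°	-65	180	180	180
ARG	mtt85°	-65	180	180	85
ARG	ptm-85°	65	180	-65	-85
ARG	ptm180°	65	180	-65	180
ARG	ptp180°	65	180	65	180
ARG	ptp85°	65	180	65	85
ARG	ptt-85°	65	180	180	-85
ARG	ptt180°	65	180	180	180
ARG	ptt85°	65	180	180	85
ASN	m-20°	-65	-20		
ASN	m-80°	-65	-80		
ASN	m120°	-65	120		
ASN	p-10°	65	-10		
ASN	p30°	65	30		
ASN	t-20°	180	-20		
ASN	t30°	180	30		
ASP	m-20°	-65	-20		
ASP	p-10°	65	-10		
ASP	p30°	65	30		
ASP	t0°	180	0		
ASP	t70°	180	70		
CYS	m	-65			
CYS	p	65			
CYS	t	180			
GLN	mm-40°	-65	-65	-40	
GLN	mm100°	-65	-65	100	
GLN	mp0°	-65	65	0	
GLN	mt-30°	-65	180	-30	
GLN	pm0°	65	-65	0	
GLN	pt20°	65	180	20	
GLN	tp-100°	180	65	-100	
GLN	tp60°	180	65	60	
GLN	tt0°	180	180	0	
GLU	mm-40°	-65	-65	-40	
GLU	mp0°	-65	65	0	
GLU	mt-10°	-65	180	-10	
GLU	pm0°	65	-65	0	
GLU	pt-20°	65	180	-20	
GLU	tm-20°	180	-65	-20	
GLU	tp10°	180	65	10	
GLU	tt0°	180	180	0	
HIS	m-70°	-65	-70		
HIS	m170°	-65	170		
HIS	m80°	-65	80		
HIS	p-80°	65	-80		
HIS	p80°	65	80		
HIS	t-160°	180	-160		
HIS	t-80°	180	-80		
ILE	mm	-65	-65		
ILE	mp	-65	65		
ILE	mt	-65	180		
ILE	pp	65	65		
ILE	pt	65	180		
ILE	tp	180	65		
ILE	tt	180	180		
LEU	mp	-65	65		
LEU	mt	-65	180		
LEU	pp	65	65		
LEU	tp	180	65		
LEU	tt	180	180		
LYS	mmmt	-65	-65	-65	180
LYS	mmtm	-65	-65	180	-65
LYS	mmtp	-65	-65	180	65
LYS	mmtt	-65	-65	180	180
LYS	mptt	-65	65	180	180
LYS	mtmm	-65	180	-65	-65
LYS	mtmt	-65	180	-65	180
LYS	mtpp	-65	180	65	65
LYS	mtpt	-65	180	65	180
LYS	mttm	-65	180	180	-65
LYS	mttp	-65	180	180	65
LYS	mttt	-65	180	180	180
LYS	ptmt	65	180	-65	180
LYS	ptpt	65	180	65	180
LYS	pttm	65	180	180	-65
LYS	pttp	65	180	180	65
LYS	pttt	65	180	180	180
LYS	tptm	180	65	180	-65
LYS	tptp	180	65	180	65
LYS	tptt	180	65	180	180
LYS	ttmm	180	180	-65	-65
LYS	ttmt	180	180	-65	180
LYS	ttpp	180	180	65	65
LYS	ttpt	180	180	65	180
LYS	tttm	180	180	180	-65
LYS	tttp	180	180	180	65
LYS	tttt	180	180	180	180
MET	mmm	-65	-65	-65	
MET	mmp	-65	-65	65	
MET	mmt	-65	-65	180	
MET	mtm	-65	180	-65	
MET	mtp	-65	180	65	
MET	mtt	-65	180	180	
MET	ptm	65	180	-65	
MET	ptp	65	180	65	
MET	tpp	180	65	65	
MET	tpt	180	65	180	
MET	ttm	180	180	-65	
MET	ttp	180	180	65	
MET	ttt	180	180	180	
PHE	m-30°	-65	-30		
PHE	m-85°	-65	-85		
PHE	p90°	65	90		
PHE	t80°	180	80		
PRO	Cγ Endo	30			
PRO	Cγ Exo	-30			
SER	m	-65			
SER	p	65			
SER	t	180			
THR	m	-65			
THR	p	65			
THR	t	180			
TRP	m-90°	-65	-90		
TRP	m0°	-65	0		
TRP	m95°	-65	95		
TRP	p-90°	65	-90		
TRP	p90°	65	90		
TRP	t-105°	180	-105		
TYR	m-30°	-65	-30		
TYR	m-85°	-65	-85		
TYR	p90°	65	90		
TYR	t80°	180	80		
VAL	m	-65			
VAL	p	65			
VAL	t	180			
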