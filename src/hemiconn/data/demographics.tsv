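case	group	hemisphere_removed	etiology	onset	age_surgery	sex	hand	age	fsiq	vci	poi
RHS1	RHS	R	CD	birth	3m	M	R	22	80	91	72
RHS2	RHS	R	RS	11y	20y	M	R	23	105	109	93
RHS3	RHS	R	PNS	8y	15y	F	R	21	96	101	86
LHS4	LHS	L	PNS	3y	6y	F	L	26	95	101	95
CNT1	CNT	na	na	na	na	M	R	26	94	99	92
CNT2	CNT	na	na	na	na	F	R	24	100	104	96
CNT3	CNT	na	na	na	na	F	L	28	100	106	94
CNT4	CNT	na	na	na	na	M	R	24	101	105	96
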