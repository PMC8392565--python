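case	MSCEIT_Exp	MSCEIT_Rea	PANAS_Pos	PANAS_Neg	STAI_State	STAI_Trait	SRS2	EQ	SQ
RHS1	0.61	-0.38	2.21	-0.75	-1.00	-0.50	-0.50	1.64	1.40
RHS2	-0.45	0.57	-0.37	-1.05	-1.20	-1.20	-1.00	2.24	0.30
RHS3	0.28	-0.16	-1.59	-1.05	-0.10	1.00	0.80	-1.15	-0.40
LHS4	-0.42	-0.66	-1.32	-0.01	1.40	1.10	1.40	-0.27	1.16
CNT1						0	0.30	-1.38	-0.79
CNT2	0.09	-0.47				1.00	1.40	0.27	0.54
CNT3	0.03	0.36				1.30	0.30	0.71	0.02
CNT4						2.00	1.30	-0.52	-0.53
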