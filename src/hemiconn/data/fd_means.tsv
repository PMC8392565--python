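case	run1	run2
RHS1	0.10
RHS2	0.13	0.20
RHS3	0.15	0.11
LHS1	0.23	0.12
CNT1	0.30
CNT2	0.14
CNT3	0.11
CNT4	0.16
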