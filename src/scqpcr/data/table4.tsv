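gene	classical	intermediate	non_classical
ACTB	0.86	0.68	0.97
ADAM17	0.00	0.00	0.00
BAX	0.00	0.00	0.00
BCL2	0.00	0.00	0.00
BCL2L1	0.94	0.00	0.00
C1QA	1.00	0.00	0.00
CCR1	0.00	0.00	0.31
CCR2	0.03	1.00	1.00
CCR5	1.00	0.99	1.00
CCR9	1.00	1.00	1.00
CD14	0.86	0.00	0.00
CD163	0.00	0.15	1.00
CD209	0.94	0.99	1.00
CD33	0.02	0.00	0.00
CD36	0.11	0.00	0.49
CD40	0.00	0.00	0.00
CD68	0.70	0.99	0.99
CD74	0.76	0.95	0.98
CD93	0.00	0.00	0.00
CLEC4E	0.00	1.00	1.00
CSF1R	0.00	0.94	0.00
CST3	0.52	0.62	0.88
CTSB	0.25	0.75	0.70
CTSK	0.00	0.00	0.00
CTSL	1.00	0.00	0.00
CTSS	0.85	0.99	0.99
CX3CR1	0.00	0.00	0.00
FCGR3A	0.05	0.96	0.95
HLA-DRA	0.90	0.94	0.61
HLA-DRB1	0.00	0.92	0.02
HMOX1	0.00	0.84	0.98
IL10	0.00	0.49	1.00
IL12A	0.00	0.00	0.00
IL15	0.00	0.00	0.00
IL18	0.00	0.00	0.24
IL1B	0.07	0.00	0.67
IL23A	0.00	0.00	0.00
IL6	1.00	1.00	1.00
IRF4	1.00	0.98	0.99
IRF5	0.00	0.72	0.00
IRF8	0.00	0.00	0.00
ITGAE	1.00	1.00	1.00
ITGAL	0.00	0.83	0.95
ITGAM	0.00	0.00	0.00
ITGAX	0.99	0.86	0.95
LTB	0.99	0.00	0.00
MARCO	0.00	0.00	0.00
MICA	0.98	1.00	0.99
MICB	0.00	0.00	0.00
MMP1	0.00	0.00	0.00
MMP2	1.00	1.00	0.99
MMP3	0.00	0.00	0.00
MMP7	0.34	0.03	0.22
MMP9	1.00	1.00	1.00
MSR1	0.92	0.00	0.00
NFKB1	0.00	0.00	0.00
PTPRC	0.96	0.72	0.95
RAET1E	1.00	0.97	0.99
RAET1G	1.00	1.00	1.00
RAET1L	0.86	0.12	0.67
RARA	0.98	1.00	0.83
RELA	0.00	0.00	0.00
S100A4	0.82	0.95	0.91
SELL	0.97	0.00	0.00
SERPINA1	0.99	0.96	0.99
SERPINB2	0.34	1.00	1.00
SIGLEC10	0.00	0.10	0.70
SIRPA	0.25	0.00	0.01
TIMP1	0.96	0.93	0.90
TLR2	0.85	0.72	0.04
TLR3	1.00	1.00	1.00
TLR4	0.00	0.00	0.00
TLR7	1.00	0.02	1.00
TLR8	0.00	0.00	0.00
TLR9	0.00	0.00	0.00
TNF	0.00	0.00	0.70
TNFSF15	0.83	0.80	0.75
TREM1	0.66	0.00	0.00
TREM2	1.00	1.00	1.00
ULBP3	0.00	0.00	0.00
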