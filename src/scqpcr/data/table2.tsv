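gene	classical	intermediate	non_classical	p_c_vs_i	p_c_vs_nc	p_i_vs_nc
ACTB	16.3	16.9	16.6	1.40E-09	2.40E-03	4.20E-03
ADAM17	5.9	5.8	6.6	9.50E-01	3.00E-01	2.60E-01
BAX	5.2	7.4	6.4	9.90E-04	8.90E-02	1.20E-01
BCL2	2.6	3	2.5	4.80E-01	8.30E-01	3.60E-01
BCL2L1	0.8	2.4	2.1	3.30E-03	1.80E-02	5.90E-01
C1QA	0.1	2.7	3.1	3.80E-07	5.20E-09	5.90E-01
CCR1	3.6	3.1	1.2	3.60E-01	1.70E-05	4.70E-04
CCR2	1.4	0.4	0	9.50E-03	9.40E-05	4.60E-02
CCR5	0	1	0	1.80E-03		2.30E-03
CCR7	0	0	0
CCR9	0.4	0.1	0.1	1.70E-03	1.70E-02	3.90E-01
CD14	11.7	7.3	4.6	8.80E-17	3.40E-32	7.70E-05
CD163	5.4	1.3	0	1.30E-09	8.30E-19	2.40E-04
CD209	1.1	0.7	0.4	1.20E-01	3.80E-03	2.10E-01
CD33	9.3	8	5.5	1.70E-02	1.50E-09	1.20E-04
CD36	10.3	7.1	1	1.60E-06	1.90E-45	1.00E-18
CD40	6	7.4	5	4.00E-02	1.50E-01	5.30E-04
CD68	14.2	14.9	13.8	4.90E-10	2.40E-01	1.70E-03
CD74	14.9	16.2	14.6	1.30E-16	2.80E-02	2.80E-23
CD93	6.8	5	2.3	5.60E-03	8.10E-12	3.70E-05
CLEC4E	2.2	0.3	0	5.40E-05	1.30E-06	9.70E-02
CSF1R	5.4	10.2	8.9	2.80E-13	3.70E-07	9.70E-03
CST3	13.4	14.3	12.7	3.60E-17	1.60E-02	1.60E-08
CTSB	11.5	12.4	11.1	4.00E-02	5.00E-01	1.80E-03
CTSK	2.5	2.4	1.7	9.60E-01	1.60E-01	1.70E-01
CTSL	0.3	5.2	3.7	1.20E-13	4.80E-09	6.30E-02
CTSS	14.7	14.3	13.8	2.60E-05	1.50E-08	5.00E-04
CX3CR1	5.7	5.1	5	1.90E-01	1.20E-01	7.80E-01
FCGR3A	8.1	11.9	12.3	1.00E-13	3.60E-20	1.50E-01
HLA-DRA	13.2	14.7	12.4	4.00E-15	2.00E-02	1.70E-11
HLA-DRB1	5.4	0.9	2	1.00E-09	2.00E-05	5.30E-02
HMOX1	8.9	12.2	12	3.60E-10	5.00E-08	4.60E-01
IL10	2.4	1.2	0.1	2.30E-02	1.50E-06	1.40E-03
IL12A	5.8	7.6	7	1.60E-03	3.80E-02	3.40E-01
IL15	2.2	2.5	2.9	6.60E-01	2.70E-01	5.00E-01
IL18	2.7	2.9	0.9	7.50E-01	1.80E-03	4.40E-04
IL1B	1.7	3.3	1.1	3.40E-02	2.60E-01	1.80E-03
IL23A	3.3	3.9	3.9	2.20E-01	1.60E-01	1.00E+00
IL6	0	0.1	0.3	3.10E-01	7.50E-02	3.90E-01
IRF4	0.1	0.6	0.6	7.40E-02	1.30E-01	9.10E-01
IRF5	7.1	9.9	8.6	4.20E-07	1.10E-02	6.90E-03
IRF8	6.8	8.1	2.9	6.50E-02	5.20E-08	8.30E-15
ITGAE	0.1	0.3	0.1	4.10E-01	6.20E-01	1.90E-01
ITGAL	7.6	11.4	12	1.70E-10	3.40E-15	2.50E-02
ITGAM	9.8	8.5	2.6	5.20E-02	1.70E-23	1.60E-15
ITGAX	10.5	12.2	11.6	4.90E-09	1.30E-03	6.40E-03
LTB	0.5	2.8	3.4	9.80E-07	7.60E-09	3.50E-01
MARCO	4.3	6.7	2.2	1.30E-03	2.30E-03	2.40E-10
MICA	0.8	0.5	0.8	5.70E-01	9.60E-01	5.20E-01
MICB	3.1	4.7	3.7	1.80E-02	3.40E-01	1.70E-01
MMP1	7.3	7.3	7.5	9.90E-01	7.60E-01	7.80E-01
MMP12	0	0	0	9.20E-01	7.40E-01	8.10E-01
MMP2	0.3	0.7	0.5	8.90E-02	3.20E-01	4.50E-01
MMP3	3.8	6.1	5.7	7.30E-05	7.50E-04	6.10E-01
MMP7	2.5	3.4	2.5	1.40E-02	8.70E-01	9.20E-03
MMP9	0.1	0	0.1	3.20E-01	9.50E-01	3.10E-01
MRC1	0	0	0
MSR1	0.8	3.7	4.4	2.90E-06	1.00E-08	3.60E-01
NFKB1	4.2	5.8	4.1	4.10E-02	9.10E-01	2.90E-02
PTPRC	8.8	11	10	5.40E-34	2.10E-15	1.10E-10
RAET1E	0.1	0.4	0.4	5.20E-05	4.90E-04	4.00E-01
RAET1G	0	0.1	0	1.60E-01		1.60E-01
RAET1L	1.1	2.1	1.5	9.50E-03	3.20E-01	1.40E-01
RARA	11.8	11.8	11.6	8.50E-01	6.20E-01	5.70E-01
RELA	6.4	8.2	5.2	1.70E-02	1.10E-01	4.50E-05
S100A4	13.1	13.8	13.3	1.00E-08	2.70E-01	2.50E-02
SELL	11.9	7.3	2.4	7.90E-15	7.60E-43	4.30E-12
SERPINA1	13.2	13.9	13.1	4.90E-09	7.50E-01	1.40E-02
SERPINB2	0.9	0.1	0	5.00E-03	1.40E-03	3.20E-01
SIGLEC10	4.6	10	10.1	1.50E-15	1.00E-16	9.50E-01
SIRPA	9.4	7.4	4.1	3.20E-04	5.50E-19	1.10E-07
TIMP1	11.7	13	12.2	2.70E-10	1.50E-01	1.20E-02
TLR2	10	9	8.8	1.90E-02	1.40E-02	7.70E-01
TLR3	0	0	0.1		3.10E-01	3.10E-01
TLR4	8.4	8	7.6	4.20E-01	1.50E-01	5.00E-01
TLR7	0.2	1.5	0.5	1.70E-03	3.20E-01	3.10E-02
TLR8	4.7	5.3	5	4.40E-01	6.90E-01	7.10E-01
TLR9	3.8	4.2	4.6	4.30E-01	2.00E-01	6.00E-01
TNF	5.8	8.4	9.8	6.30E-04	8.00E-10	2.90E-02
TNFSF15	5.8	7	6.4	2.40E-05	1.90E-02	4.50E-03
TREM1	11.2	7.8	4.4	1.60E-08	2.40E-18	9.50E-05
TREM2	0.1	0	0	3.20E-01	3.30E-01
ULBP1	0	0	0
ULBP2	0	0	0		3.10E-01	3.10E-01
ULBP3	3.8	5.2	5	3.00E-02	8.20E-02	7.00E-01
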