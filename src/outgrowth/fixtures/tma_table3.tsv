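# COMMD3 IHC category (0-4) counts by clinicopathological parameter,
# transcribed from the published tissue-microarray association table.
# One row per parameter level; "(total)" rows are the printed column totals
# and act as a transcription checksum.  printed_p is the p-value string as
# printed for the block ("ns" = not significant).
block	parameter	level	cat0	cat1	cat2	cat3	cat4	printed_p
age	Age at diagnosis	< 50 years	139	74	56	11	27	ns
age	Age at diagnosis	>= 50 years	54	30	21	12	15	ns
age	Age at diagnosis	(total)	193	104	77	23	42	ns
stage	Stage	I	11	8	6	1	2	ns
stage	Stage	II	56	22	17	2	7	ns
stage	Stage	III	5	2	2	1	4	ns
stage	Stage	(total)	72	32	25	4	13	ns
grade	Grade	1	21	15	8	5	12	5.80E-02
grade	Grade	2	98	52	45	13	24	5.80E-02
grade	Grade	3	80	41	27	8	8	5.80E-02
grade	Grade	(total)	199	108	80	26	44	5.80E-02
mitotic	Mitotic score	1	108	57	48	17	29	5.80E-02
mitotic	Mitotic score	2	25	15	12	2	12	5.80E-02
mitotic	Mitotic score	3	65	36	20	7	3	5.80E-02
mitotic	Mitotic score	(total)	198	108	80	26	44	5.80E-02
tubule	Tubule score	T1/2	35	28	21	7	22	3.00E-04
tubule	Tubule score	T3	164	80	59	19	22	3.00E-04
tubule	Tubule score	(total)	199	108	80	26	44	3.00E-04
erher2_erneg	ER/HER2 subtype (ER-)	ER-/HER2-	47	18	10	2	0	5.40E-05
erher2_erneg	ER/HER2 subtype (ER-)	ER-/HER2+	9	3	10	2	5	5.40E-05
erher2_erneg	ER/HER2 subtype (ER-)	(total)	56	21	20	4	5	5.40E-05
erher2_erpos	ER/HER2 subtype (ER+)	ER+/HER2-	133	80	52	19	36	ns
erher2_erpos	ER/HER2 subtype (ER+)	ER+/HER2+	8	6	7	3	3	ns
erher2_erpos	ER/HER2 subtype (ER+)	(total)	141	86	59	22	39	ns
histotype	Histological type	IC (NST)	112	59	62	16	24	5.50E-02
histotype	Histological type	ILC & variants	29	11	8	5	8	5.50E-02
histotype	Histological type	mixed ducto-lob	18	13	3	0	4	5.50E-02
histotype	Histological type	mixed IC + special type	20	9	3	1	2	5.50E-02
histotype	Histological type	metaplastic	8	3	3	2	0	5.50E-02
histotype	Histological type	special types	12	12	1	2	6	5.50E-02
histotype	Histological type	(total)	199	107	80	26	44	5.50E-02
prognostic	Prognostic subgroups	HER2+	17	9	17	5	8	4.40E-02
prognostic	Prognostic subgroups	ER+ (Ki67-low)	114	67	43	14	30	4.40E-02
prognostic	Prognostic subgroups	ER+ (Ki67-high)	11	7	5	2	4	4.40E-02
prognostic	Prognostic subgroups	TN (basal-like)	35	15	7	2	0	4.40E-02
prognostic	Prognostic subgroups	TN (non-basal)	8	3	3	0	0	4.40E-02
prognostic	Prognostic subgroups	(total)	185	101	75	23	42	4.40E-02
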