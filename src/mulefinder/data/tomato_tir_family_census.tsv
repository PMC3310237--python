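family	copies	with_tsd	pct_tsd	autonomous	pct_autonomous
SLMULE56	8	1	12.5	0	0.0
SLMULE22	11	3	27.3	0	0.0
SLMULE28	13	4	30.8	0	0.0
SLMULE07	25	5	20.0	3	12.0
SLMULE48	26	7	26.9	0	0.0
SLMULE50	34	2	5.9	0	0.0
SLMULE49	40	1	2.5	2	5.0
SLMULE34	42	1	2.4	0	0.0
SLMULE25	49	13	26.5	9	18.4
SLMULE52	56	11	19.6	0	0.0
SLMULE44	62	2	3.2	1	1.6
SLMULE38	68	22	32.4	10	14.7
SLMULE31	71	5	7.0	3	4.2
SLMULE39	88	26	29.5	3	3.4
SLMULE54	100	28	28.0	12	12.0
SLMULE43	106	63	59.4	35	33.0
SLMULE47	109	25	22.9	0	0.0
SLMULE17	112	4	3.6	5	4.5
SLMULE45	112	12	10.7	2	1.8
SLMULE20	114	36	31.6	0	0.0
SLMULE53	116	8	6.9	3	2.6
SLMULE10	118	3	2.5	35	29.7
SLMULE11	130	43	33.1	7	5.4
SLMULE59	144	49	34.0	2	1.4
SLMULE42	156	6	3.8	1	0.6
SLMULE27	164	72	43.9	19	11.6
SLMULE29	164	64	39.0	1	0.6
SLMULE16	167	40	24.0	4	2.4
SLMULE30	176	31	17.6	1	0.6
SLMULE51	210	64	30.5	1	0.5
SLMULE23	233	84	36.1	1	0.4
SLMULE04	250	4	1.6	2	0.8
SLMULE58	262	66	25.2	2	0.8
SLMULE26	266	56	21.1	0	0.0
SLMULE13	273	73	26.7	94	34.4
SLMULE55	275	87	31.6	2	0.7
SLMULE57	337	178	52.8	10	3.0
SLMULE40	361	173	47.9	20	5.5
SLMULE36	373	100	26.8	17	4.6
SLMULE24	381	96	25.2	4	1.0
SLMULE41	413	126	30.5	3	0.7
SLMULE46	418	62	14.8	2	0.5
SLMULE32	444	199	44.8	62	14.0
SLMULE15	455	130	28.6	9	2.0
SLMULE18	498	198	39.8	11	2.2
SLMULE03	546	193	35.3	10	1.8
SLMULE37	635	361	56.9	40	6.3
SLMULE08	644	133	20.7	4	0.6
SLMULE09	760	425	55.9	26	3.4
SLMULE35	823	407	49.5	30	3.6
SLMULE14	1144	236	20.6	1	0.1
SLMULE21	1301	73	5.6	7	0.5
SLMULE33	1310	548	41.8	16	1.2
SLMULE05	1341	110	8.2	7	0.5
SLMULE06	1621	816	50.3	18	1.1
SLMULE02	1685	748	44.4	1	0.1
SLMULE12	1798	748	41.6	5	0.3
SLMULE19	2386	914	38.3	3	0.1
SLMULE01	4017	2609	64.9	3	0.1
Total	28041	10604	38	569	2
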