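id	chrom	start	end	size	tsd	outer_tir_identity	inner_tir_identity
PM-ZIBP-1	0	12038207	12039150	944	TTTTAAATT	87	N/A
PM-ZIBP-2	2	29724087	29725458	1372	TAAATTATA	94	92
PM-ZIBP-3	2	33667391	33668737	1347	TACATTTTAA	92	90
PM-ZIBP-4	3	50199015	50200383	1369	TTAAAATTA	91	93
PM-ZIBP-5	4	4315606	4316970	1365	TATTATAAA	95	90
PM-ZIBP-6	4	58126752	58128120	1369	GTCAGGTTAA	93	91
PM-ZIBP-7	5	10380074	10381444	1371	ATAAAAGAT	93	92
PM-ZIBP-8	6	29844899	29846272	1374	CTTCGAGAC	91	92
PM-ZIBP-9	6	41871484	41872853	1370	TTTATTTAC	90	89
PM-ZIBP-10	6	42030690	42032062	1373	TTAAAAAAA	92	92
PM-ZIBP-11	6	7121877	7123250	1374	TTAAAAGAA	90	90
PM-ZIBP-12	8	14577081	14578450	1370	GAATAATAA	93	91
PM-ZIBP-13	8	4530978	4532348	1371	TTTTGGGAA	93	89
PM-ZIBP-14	12	9912832	9914208	1377	TATTTTTAT	92	90
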