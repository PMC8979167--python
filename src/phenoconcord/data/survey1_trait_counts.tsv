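# Published Survey-1 per-trait count columns (totals over all raters and
# larvae) together with the printed derived metrics. The derived columns
# (terms_per_tag, terms_per_trait) are recomputed from the count columns by
# the heterogeneity module and compared cell-by-cell in tests. Blank cells in
# the "hatched" row are blank in the source.
general_trait	curie	total_tags	unique_terms	child_traits	n_larvae	terms_per_tag	terms_per_trait
abnormal	ZP:0005632	24	7	0	22	0.29	7
abnormal axis	ZP:0127724	71	15	1	12	0.21	8
abnormal body length	ZP:0012799	82	16	1	18	0.20	8
abnormal brain	ZP:0000100	40	7	0	16	0.18	7
abnormal eye	ZP:0000943	77	12	1	15	0.16	6
abnormal gut	ZP:0002008	8	6	1	4	0.75	3
abnormal head	ZP:0001609	127	30	3	23	0.24	8
abnormal heart	ZP:0000107	249	28	2	20	0.11	9
abnormal jaw	ZP:0007203	153	24	2	24	0.16	8
abnormal notochord	ZP:0000624	49	22	4	8	0.45	4
abnormal otic vesicle	ZP:0001601	41	21	0	8	0.51	21
abnormal pectoral fin	ZP:0001610	14	12	0	13	0.86	12
abnormal pigmentation	ZP:0015121	29	12	1	12	0.41	6
abnormal snout	ZP:0014550	78	5	0	22	0.06	5
abnormal swim bladder	ZP:0127709	221	34	3	20	0.15	9
abnormal tail	ZP:0001129	79	33	3	16	0.42	8
abnormal trunk	ZP:0003437	43	3	0	12	0.07	3
abnormal yolk	ZP:0002676	274	53	5	23	0.19	9
dead	ZP:0000306	2	2	0	1	1.00	2
necrosis	ZP:0000398	12	8	0	5	0.67	8
normal		51	17	0	9	0.33	17
hatched		24	1			0.04
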