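# Two-level trait catalog: 21 general categories (20 with published CURIEs plus
# the CURIE-less "normal" category) and 27 granular children. Granular CURIEs
# other than the three published tail children are not printed in the source
# tables; placeholder ZP:UNSPEC_* identifiers (provenance "placeholder") keep
# the per-trait child counts correct. Labels are used where the granular trait
# is named in prose. "hatched" is a special status category outside the catalog.
granular_curie	general_curie	label	provenance
ZP:0005632	ZP:0005632	abnormal	published
ZP:0127724	ZP:0127724	abnormal axis	published
ZP:0012799	ZP:0012799	abnormal body length	published
ZP:0000100	ZP:0000100	abnormal brain	published
ZP:0000943	ZP:0000943	abnormal eye	published
ZP:0002008	ZP:0002008	abnormal gut	published
ZP:0001609	ZP:0001609	abnormal head	published
ZP:0000107	ZP:0000107	abnormal heart	published
ZP:0007203	ZP:0007203	abnormal jaw	published
ZP:0000624	ZP:0000624	abnormal notochord	published
ZP:0001601	ZP:0001601	abnormal otic vesicle	published
ZP:0001610	ZP:0001610	abnormal pectoral fin	published
ZP:0015121	ZP:0015121	abnormal pigmentation	published
ZP:0014550	ZP:0014550	abnormal snout	published
ZP:0127709	ZP:0127709	abnormal swim bladder	published
ZP:0001129	ZP:0001129	abnormal tail	published
ZP:0003437	ZP:0003437	abnormal trunk	published
ZP:0002676	ZP:0002676	abnormal yolk	published
ZP:0000306	ZP:0000306	dead	published
ZP:0000398	ZP:0000398	necrosis	published
normal	normal	normal	published
ZP:0004969	ZP:0001129	abnormal tail fin	published
ZP:0010319	ZP:0001129	abnormally curved tail	published
ZP:0001130	ZP:0001129	abnormally short tail	published
ZP:UNSPEC_01	ZP:0127724	abnormally curved axis	placeholder
ZP:UNSPEC_02	ZP:0012799	unspecified child of abnormal body length	placeholder
ZP:UNSPEC_03	ZP:0000943	abnormally small eye	placeholder
ZP:UNSPEC_04	ZP:0002008	unspecified child of abnormal gut	placeholder
ZP:UNSPEC_05	ZP:0001609	abnormally small head	placeholder
ZP:UNSPEC_06	ZP:0001609	abnormally necrotic head	placeholder
ZP:UNSPEC_07	ZP:0001609	hemorrhagic head	placeholder
ZP:UNSPEC_08	ZP:0000107	pericardial edema	placeholder
ZP:UNSPEC_09	ZP:0000107	unspecified child of abnormal heart	placeholder
ZP:UNSPEC_10	ZP:0007203	abnormally small jaw	placeholder
ZP:UNSPEC_11	ZP:0007203	abnormally large jaw	placeholder
ZP:UNSPEC_12	ZP:0000624	unspecified child 1 of abnormal notochord	placeholder
ZP:UNSPEC_13	ZP:0000624	unspecified child 2 of abnormal notochord	placeholder
ZP:UNSPEC_14	ZP:0000624	unspecified child 3 of abnormal notochord	placeholder
ZP:UNSPEC_15	ZP:0000624	unspecified child 4 of abnormal notochord	placeholder
ZP:UNSPEC_16	ZP:0015121	unspecified child of abnormal pigmentation	placeholder
ZP:UNSPEC_17	ZP:0127709	unspecified child 1 of abnormal swim bladder	placeholder
ZP:UNSPEC_18	ZP:0127709	unspecified child 2 of abnormal swim bladder	placeholder
ZP:UNSPEC_19	ZP:0127709	unspecified child 3 of abnormal swim bladder	placeholder
ZP:UNSPEC_20	ZP:0002676	yolk sac edema	placeholder
ZP:UNSPEC_21	ZP:0002676	abnormally large yolk	placeholder
ZP:UNSPEC_22	ZP:0002676	unspecified child 1 of abnormal yolk	placeholder
ZP:UNSPEC_23	ZP:0002676	unspecified child 2 of abnormal yolk	placeholder
ZP:UNSPEC_24	ZP:0002676	unspecified child 3 of abnormal yolk	placeholder
hatched	hatched	hatched	special
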