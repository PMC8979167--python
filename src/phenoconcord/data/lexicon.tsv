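# Curated verbatim -> CURIE lexicon. "Table 1" rows are the published worked
# example for the abnormal-tail trait; "curator" rows cover the special
# non-malformation categories.
verbatim	curie	provenance
Malformation tail	ZP:0001129	Table 1
tail deformation	ZP:0001129	Table 1
malformation tail	ZP:0001129	Table 1
length of the tail	ZP:0001129	Table 1
caudal fin malformation	ZP:0004969	Table 1
caudal fin malformations	ZP:0004969	Table 1
malformed caudal fin	ZP:0004969	Table 1
Cfin	ZP:0004969	Table 1
cfin	ZP:0004969	Table 1
Malformation tail fin	ZP:0004969	Table 1
Tail End Vacuolization	ZP:0004969	Table 1
ruffled fin	ZP:0004969	Table 1
tail tip necrosis	ZP:0004969	Table 1
vacuolization in end of tail	ZP:0004969	Table 1
Curved tail	ZP:0010319	Table 1
Slightly Curved Tail	ZP:0010319	Table 1
bent tail tip	ZP:0010319	Table 1
C tail	ZP:0010319	Table 1
C-tail	ZP:0010319	Table 1
bend tail	ZP:0010319	Table 1
curved tail	ZP:0010319	Table 1
curved tail tip	ZP:0010319	Table 1
slightly curved tail	ZP:0010319	Table 1
slight tail curve	ZP:0010319	Table 1
tail curve	ZP:0010319	Table 1
tail tip curve	ZP:0010319	Table 1
tail bending	ZP:0010319	Table 1
abnormal tail curvature	ZP:0010319	Table 1
Possible Short Tail	ZP:0001130	Table 1
short tail	ZP:0001130	Table 1
possible short tail	ZP:0001130	Table 1
reduced tail length	ZP:0001130	Table 1
normal	normal	curator
dead	ZP:0000306	curator
hatched	hatched	curator
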