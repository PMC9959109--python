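# E. coli core carbon-transition network for aerobic growth on glucose.
# Pathways: EMP, pentose phosphate (ping-pong TK/TA half reactions via the
# bound C2/C3 carrier pools TKC2/TAC3), Entner-Doudoroff, TCA cycle,
# glyoxylate shunt, anaplerosis (PEP carboxylase, OAA decarboxylation, malic
# enzyme), FBPase/PEP-synthetase futile partners, both acetate routes
# (reversible Pta-AckA, irreversible PoxB), explicit amino acid and one-carbon
# biosynthesis, serine/threonine glycine routes with irreversible glycine
# cleavage, serine deaminase, nucleotide-linked Asp->Fum amino-donor transfer,
# biomass drain and explicit CO2 exchange with the environment.
# Dual atom maps separated by ';' encode molecular symmetry (succinate,
# fumarate) as equally weighted alternatives.
reaction_id	equation	atom_map	reversible	kind	lower	upper
pts	1 GLC_ext + 1 PEP -> 1 G6P + 1 PYR	abcdef + ghi -> abcdef + ghi	no	uptake	0	inf
pgi	1 G6P -> 1 F6P	abcdef -> abcdef	yes	internal	-inf	inf
pfk	1 F6P -> 1 FBP	abcdef -> abcdef	no	internal	0	inf
fbp	1 FBP -> 1 F6P	abcdef -> abcdef	no	internal	0	inf
fba	1 FBP -> 1 DHAP + 1 GAP	abcdef -> cba + def	yes	internal	-inf	inf
tpi	1 DHAP -> 1 GAP	abc -> cba	yes	internal	-inf	inf
gapd	1 GAP -> 1 PG3	abc -> abc	yes	internal	-inf	inf
eno	1 PG3 -> 1 PEP	abc -> abc	yes	internal	-inf	inf
pyk	1 PEP -> 1 PYR	abc -> abc	no	internal	0	inf
pps	1 PYR -> 1 PEP	abc -> abc	no	internal	0	inf
zwf	1 G6P -> 1 PG6	abcdef -> abcdef	no	internal	0	inf
gnd	1 PG6 -> 1 RU5P + 1 CO2	abcdef -> bcdef + a	no	internal	0	inf
edd	1 PG6 -> 1 PYR + 1 GAP	abcdef -> abc + def	no	internal	0	inf
rpi	1 RU5P -> 1 R5P	abcde -> abcde	yes	internal	-inf	inf
rpe	1 RU5P -> 1 X5P	abcde -> abcde	yes	internal	-inf	inf
tkt1	1 X5P -> 1 TKC2 + 1 GAP	abcde -> ab + cde	yes	internal	-inf	inf
tkt2	1 F6P -> 1 TKC2 + 1 E4P	abcdef -> ab + cdef	yes	internal	-inf	inf
tkt3	1 S7P -> 1 TKC2 + 1 R5P	abcdefg -> ab + cdefg	yes	internal	-inf	inf
tal1	1 F6P -> 1 TAC3 + 1 GAP	abcdef -> abc + def	yes	internal	-inf	inf
tal2	1 S7P -> 1 TAC3 + 1 E4P	abcdefg -> abc + defg	yes	internal	-inf	inf
pdh	1 PYR -> 1 ACCOA + 1 CO2	abc -> bc + a	no	internal	0	inf
cs	1 OAA + 1 ACCOA -> 1 ICIT	abcd + ef -> abcdef	no	internal	0	inf
idh	1 ICIT -> 1 AKG + 1 CO2	abcdef -> dcbfe + a	no	internal	0	inf
akgdh	1 AKG -> 1 SUC + 1 CO2	abcde -> bcde + a	no	internal	0	inf
sdh	1 SUC -> 1 FUM	abcd -> abcd; abcd -> dcba	yes	internal	-inf	inf
fum	1 FUM -> 1 MAL	abcd -> abcd; abcd -> dcba	yes	internal	-inf	inf
mdh	1 MAL -> 1 OAA	abcd -> abcd	yes	internal	-inf	inf
icl	1 ICIT -> 1 GLX + 1 SUC	abcdef -> dc + abfe	no	internal	0	inf
ms	1 GLX + 1 ACCOA -> 1 MAL	ab + cd -> abdc	no	internal	0	inf
ppc	1 PEP + 1 CO2 -> 1 OAA	abc + d -> abcd	no	internal	0	inf
pck	1 OAA -> 1 PEP + 1 CO2	abcd -> abc + d	no	internal	0	inf
mae	1 MAL -> 1 PYR + 1 CO2	abcd -> abc + d	no	internal	0	inf
pox	1 PYR -> 1 ACE + 1 CO2	abc -> bc + a	no	internal	0	inf
pta	1 ACCOA -> 1 ACE	ab -> ab	yes	internal	-inf	inf
ace_out	1 ACE -> 1 ACE_ext	ab -> ab	no	efflux	0	inf
co2_ex	1 CO2 -> 1 CO2_ext	a -> a	yes	exchange_env	-inf	inf
ala_syn	1 PYR -> 1 ALA	abc -> abc	no	internal	0	inf
val_syn	1 PYR + 1 PYR -> 1 VAL + 1 CO2	abc + def -> abefc + d	no	internal	0	inf
leu_syn	1 ACCOA + 1 PYR + 1 PYR -> 1 LEU + 1 CO2 + 1 CO2	ab + cde + fgh -> abdghe + c + f	no	internal	0	inf
ile_syn	1 THR + 1 PYR -> 1 ILE + 1 CO2	abcd + efg -> abfcdg + e	no	internal	0	inf
phe_syn	1 PEP + 1 PEP + 1 E4P -> 1 PHE + 1 CO2	abc + def + ghij -> defbcghij + a	no	internal	0	inf
tyr_syn	1 PEP + 1 PEP + 1 E4P -> 1 TYR + 1 CO2	abc + def + ghij -> defbcghij + a	no	internal	0	inf
ser_syn	1 PG3 -> 1 SER	abc -> abc	no	internal	0	inf
shmt	1 SER -> 1 GLY + 1 METHF	abc -> ab + c	yes	internal	-inf	inf
gcs	1 GLY -> 1 CO2 + 1 METHF	ab -> a + b	no	internal	0	inf
ser_deam	1 SER -> 1 PYR	abc -> abc	no	internal	0	inf
thr_syn	1 ASP -> 1 THR	abcd -> abcd	no	internal	0	inf
gly_thr	1 THR -> 1 GLY + 1 ACCOA	abcd -> ab + cd	no	internal	0	inf
asp_syn	1 OAA -> 1 ASP	abcd -> abcd	no	internal	0	inf
glu_syn	1 AKG -> 1 GLU	abcde -> abcde	no	internal	0	inf
met_syn	1 ASP + 1 METHF -> 1 MET	abcd + e -> abcde	no	internal	0	inf
asp_fum	1 ASP -> 1 FUM	abcd -> abcd; abcd -> dcba	no	internal	0	inf
biomass	2.967377 ACCOA + 0.554418 ALA + 1.122377 ASP + 0.689513 CO2 + 0.162686 DHAP + 0.055900 E4P + 0.151662 F6P + 0.278100 G6P + 1.019151 GLU + 0.994421 GLY + 0.274417 ILE + 0.426871 LEU + 0.147372 MET + 0.936185 METHF + 0.131731 PEP + 0.177863 PHE + 0.358518 PYR + 0.906433 R5P + 0.508248 SER + 0.238844 THR + 0.132127 TYR + 0.401462 VAL -> 1 BIOMASS		no	biomass	0	inf
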