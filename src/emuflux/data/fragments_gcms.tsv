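# GC-MS fragment panel used for flux fitting: 30 TBDMS amino-acid ions,
# two ribose and two glucose aldononitrile-propionate ions.
# Carbon subsets follow the standard TBDMS fragmentation families
# ([M-57] = C1-Cn, [M-85]/[M-159] = C2-Cn, f302 = C1-C2, [M-15] = C1-Cn);
# sugar-fragment carbon subsets and ion formulas are declared assumptions of
# this fixture (editable). Formulas are full-ion elemental compositions used
# for natural-abundance correction; backbone carbons are included in the C count.
fragment	monomer	carbons	formula
Ala232	Ala	2-3	C10H26N1O1Si2
Ala260	Ala	1-3	C11H26N1O2Si2
Gly218	Gly	2	C9H24N1O1Si2
Gly246	Gly	1-2	C10H24N1O2Si2
Val260	Val	2-5	C12H30N1O1Si2
Val288	Val	1-5	C13H30N1O2Si2
Leu274	Leu	2-6	C13H32N1O1Si2
Ile200	Ile	2-6	C11H26N1Si1
Ile274	Ile	2-6	C13H32N1O1Si2
Phe302	Phe	1-2	C14H32N1O2Si2
Phe308	Phe	2-9	C16H30N1O1Si2
Phe336	Phe	1-9	C17H30N1O2Si2
Met218	Met	2-5	C10H24N1S1Si1
Met292	Met	2-5	C12H30N1O1S1Si2
Met320	Met	1-5	C13H30N1O2S1Si2
Ser288	Ser	2-3	C14H34N1O1Si2
Ser390	Ser	1-3	C17H40N1O3Si3
Thr376	Thr	2-4	C17H42N1O2Si3
Thr404	Thr	1-4	C18H42N1O3Si3
Tyr302	Tyr	1-2	C14H32N1O2Si2
Tyr438	Tyr	2-9	C22H44N1O2Si3
Tyr466	Tyr	1-9	C23H44N1O3Si3
Tyr508	Tyr	1-9	C26H50N1O3Si3
Asp302	Asp	1-2	C14H32N1O2Si2
Asp376	Asp	2-4	C15H34N1O2Si2
Asp390	Asp	2-4	C17H40N1O3Si3
Asp418	Asp	1-4	C18H40N1O4Si3
Glu330	Glu	2-5	C16H36N1O2Si2
Glu404	Glu	2-5	C18H42N1O3Si3
Glu432	Glu	1-5	C19H42N1O4Si3
Rib173	Rib	1-2	C7H11N1O4
Rib284	Rib	1-4	C13H18N1O6
Glc173	Glc	1-2	C7H11N1O4
Glc370	Glc	1-5	C16H20N1O9
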