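# Monomer composition tables and precursor recipes used to expand measured
# macromolecular composition into a biomass drain equation (mmol per gDW).
#
# Sources: standard E. coli composition tables and EcoCyc-derived biosynthetic
# recipes. Recipes list carbon-precursor pools of the core network consumed
# per mmol of building block; small carbon releases along a route (e.g. the
# orotate decarboxylation of pyrimidine synthesis) are neglected so that every
# recipe is a pure drain -- documented approximation, kept within the 10%
# carbon-closure audit. Nitrogen donations are carried by the explicit
# asp_fum reaction of the network, not by these recipes. Users may substitute
# strain-specific values.
protein:
  # mol fractions of amino acid residues in total cell protein
  fractions:
    ala: 0.096
    arg: 0.055
    asn: 0.045
    asp: 0.045
    cys: 0.017
    gln: 0.049
    glu: 0.049
    gly: 0.115
    his: 0.018
    ile: 0.054
    leu: 0.084
    lys: 0.064
    met: 0.029
    phe: 0.035
    pro: 0.041
    ser: 0.040
    thr: 0.047
    trp: 0.011
    tyr: 0.026
    val: 0.079
  # residue (water-free) molecular weights, g/mol
  residue_mw:
    ala: 71.08
    arg: 156.19
    asn: 114.10
    asp: 115.09
    cys: 103.14
    gln: 128.13
    glu: 129.12
    gly: 57.05
    his: 137.14
    ile: 113.16
    leu: 113.16
    lys: 128.17
    met: 131.19
    phe: 147.18
    pro: 97.12
    ser: 87.08
    thr: 101.10
    trp: 186.21
    tyr: 163.18
    val: 99.13
  # precursor pools drained per mmol residue
  recipes:
    ala: {ALA: 1}
    arg: {GLU: 1, CO2: 1}
    asn: {ASP: 1}
    asp: {ASP: 1}
    cys: {SER: 1}
    gln: {GLU: 1}
    glu: {GLU: 1}
    gly: {GLY: 1}
    his: {R5P: 1, METHF: 1}
    ile: {ILE: 1}
    leu: {LEU: 1}
    lys: {ASP: 1, PYR: 1}
    met: {MET: 1}
    phe: {PHE: 1}
    pro: {GLU: 1}
    ser: {SER: 1}
    thr: {THR: 1}
    trp: {SER: 1, R5P: 1, E4P: 1, PEP: 1}
    tyr: {TYR: 1}
    val: {VAL: 1}
rna:
  fractions: {amp: 0.262, gmp: 0.322, cmp: 0.200, ump: 0.216}
  residue_mw: {amp: 329.2, gmp: 345.2, cmp: 305.2, ump: 306.2}
  recipes:
    amp: {R5P: 1, GLY: 1, METHF: 2, CO2: 1}
    gmp: {R5P: 1, GLY: 1, METHF: 2, CO2: 1}
    cmp: {R5P: 1, ASP: 1}
    ump: {R5P: 1, ASP: 1}
dna:
  fractions: {damp: 0.246, dtmp: 0.246, dgmp: 0.254, dcmp: 0.254}
  residue_mw: {damp: 313.2, dtmp: 304.2, dgmp: 329.2, dcmp: 289.2}
  recipes:
    damp: {R5P: 1, GLY: 1, METHF: 2, CO2: 1}
    dgmp: {R5P: 1, GLY: 1, METHF: 2, CO2: 1}
    dcmp: {R5P: 1, ASP: 1}
    dtmp: {R5P: 1, ASP: 1, METHF: 1}
# average-monomer recipes for the remaining macromolecular classes
plp:  # phospholipids: glycerol-3P backbone, two ~C16.5 acyl chains, PE head
  monomer_mw: 700.0
  recipe: {DHAP: 1, ACCOA: 16, SER: 1}
lps:  # lipopolysaccharide average unit: GlcN disaccharide, acyls, core sugars
  monomer_mw: 1000.0
  recipe: {F6P: 2, ACCOA: 7, G6P: 2, R5P: 1, PEP: 1}
pgl:  # murein monomer: GlcNAc-MurNAc + Ala-Glu-DAP-Ala peptide
  monomer_mw: 940.0
  recipe: {F6P: 2, ACCOA: 2, PEP: 1, ALA: 2, GLU: 1, ASP: 1, PYR: 1}
gl:   # glycogen glucosyl unit
  monomer_mw: 162.1
  recipe: {G6P: 1}
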