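# Ordered functional-group substructure catalog for the SUBSTRUCT_FP4 fingerprint.
# One pattern per line: <name><TAB><SMARTS>. Bit i of the fingerprint is set when
# pattern i matches the molecule. The catalog order is frozen: models record its
# length and any edit invalidates previously trained models.
alkyl_carbon	[CX4]
quaternary_carbon	[CX4]([#6])([#6])([#6])[#6]
alkene	[CX3]=[CX3]
alkyne	[CX2]#[CX2]
allene	[CX3]=[CX2]=[CX3]
arene	c1ccccc1
aromatic_carbon	c
aromatic_nitrogen	n
aromatic_oxygen	o
aromatic_sulfur	s
fluoride	[#6][F]
chloride	[#6][Cl]
bromide	[#6][Br]
iodide	[#6][I]
aryl_fluoride	c[F]
aryl_chloride	c[Cl]
aryl_bromide	c[Br]
aryl_iodide	c[I]
vinyl_halide	[CX3]=[CX3][F,Cl,Br,I]
trifluoromethyl	[CX4](F)(F)F
polyhalo_carbon	[CX4]([F,Cl,Br,I])[F,Cl,Br,I]
alcohol	[CX4][OX2H]
primary_alcohol	[CX4H2][OX2H]
secondary_alcohol	[CX4H1]([#6])[OX2H]
tertiary_alcohol	[CX4]([#6])([#6])([#6])[OX2H]
phenol	c[OX2H]
enol	[CX3]=[CX3][OX2H]
ether	[OD2]([#6])[#6]
dialkyl_ether	[CX4][OX2][CX4]
aryl_ether	c[OX2][#6]
diaryl_ether	c[OX2]c
methoxy	[OX2][CH3]
peroxide	[OX2][OX2]
hemiacetal	[CX4]([OX2H])[OX2][#6]
acetal	[CX4]([OX2][#6])[OX2][#6]
epoxide	C1OC1
oxetane	C1COC1
tetrahydrofuran	C1CCOC1
tetrahydropyran	C1CCOCC1
dioxolane	C1OCCO1
amine	[NX3;!$(N~[!#6;!#1]);!$(N=*);!$(N[C,S,P]=[O,S,N])]
primary_amine	[NX3H2;!$(N~[!#6;!#1]);!$(N[C,S,P]=[O,S,N])]
secondary_amine	[NX3H1]([#6])[#6]
tertiary_amine	[NX3]([#6])([#6])[#6]
aryl_amine	c[NX3]
dimethylamino	[NX3]([CH3])[CH3]
ammonium	[NX4+]
imine	[CX3]=[NX2]
oxime	[CX3]=[NX2][OX2H]
hydrazone	[CX3]=[NX2][NX3]
hydrazine	[NX3][NX3]
azo	[#6][NX2]=[NX2][#6]
azide	[NX2]=[NX2+]=[NX1-]
diazonium	[NX2+]#[NX1]
nitrile	[CX2]#[NX1]
isonitrile	[NX2+]#[CX1-]
nitro	[NX3](=O)[OX1]
nitroso	[NX2]=[OX1]
nitrate_ester	[OX2][NX3](=O)=O
cyanamide	[NX3][CX2]#[NX1]
aldehyde	[CX3H1]=[OX1]
ketone	[#6][CX3](=[OX1])[#6]
carboxylic_acid	[CX3](=[OX1])[OX2H]
carboxylate	[CX3](=[OX1])[OX1-]
ester	[#6][CX3](=[OX1])[OX2][#6]
lactone	[CX3;R](=[OX1])[OX2;R]
amide	[CX3](=[OX1])[NX3]
primary_amide	[CX3](=[OX1])[NX3H2]
secondary_amide	[CX3](=[OX1])[NX3H1][#6]
tertiary_amide	[CX3](=[OX1])[NX3]([#6])[#6]
lactam	[CX3;R](=[OX1])[NX3;R]
carbamate	[NX3][CX3](=[OX1])[OX2][#6]
urea	[NX3][CX3](=[OX1])[NX3]
guanidine	[NX3][CX3](=[NX2])[NX3]
amidine	[CX3](=[NX2])[NX3]
acyl_halide	[CX3](=[OX1])[F,Cl,Br,I]
anhydride	[CX3](=[OX1])[OX2][CX3]=[OX1]
carbonate	[OX2][CX3](=[OX1])[OX2]
alpha_beta_unsat_carbonyl	[CX3]=[CX3][CX3]=[OX1]
beta_ketoester	[CX3](=[OX1])[CX4][CX3](=[OX1])[OX2]
thiol	[#6][SX2H]
sulfide	[#6][SX2][#6]
disulfide	[SX2][SX2]
sulfoxide	[#16X3]=[OX1]
sulfone	[#16X4](=[OX1])=[OX1]
sulfonamide	[#16X4](=[OX1])(=[OX1])[NX3]
sulfonic_acid	[#16X4](=[OX1])(=[OX1])[OX2H]
sulfonate_ester	[#16X4](=[OX1])(=[OX1])[OX2][#6]
thioamide	[CX3](=[SX1])[NX3]
thioester	[#6][CX3](=[SX1])[OX2,SX2]
thiourea	[NX3][CX3](=[SX1])[NX3]
thiocyanate	[SX2][CX2]#[NX1]
isothiocyanate	[NX2]=[CX2]=[SX1]
sulfate	[OX2][SX4](=[OX1])(=[OX1])[OX2]
phosphate	[PX4](=[OX1])([OX2])([OX2])[OX2]
phosphonate	[PX4](=[OX1])([OX2])[#6]
phosphine	[PX3]
boronic_acid	[BX3]([OX2H])[OX2H]
silane	[#14]
furan	c1ccoc1
thiophene	c1ccsc1
pyrrole	c1cc[nH]c1
imidazole	c1cnc[nH]1
pyrazole	c1cc[nH]n1
oxazole	c1cnco1
isoxazole	c1ccon1
thiazole	c1cncs1
isothiazole	c1ccsn1
triazole	c1nc[nH]n1
tetrazole	c1nnn[nH]1
oxadiazole	c1nnco1
thiadiazole	c1nncs1
pyridine	c1ccncc1
pyridine_2_subst	c1ccnc(c1)[!#1]
pyrimidine	c1cncnc1
pyrazine	c1cnccn1
pyridazine	c1ccnnc1
triazine	c1ncncn1
indole	c1ccc2[nH]ccc2c1
benzimidazole	c1ccc2[nH]cnc2c1
benzofuran	c1ccc2occc2c1
benzothiophene	c1ccc2sccc2c1
benzoxazole	c1ccc2ocnc2c1
benzothiazole	c1ccc2scnc2c1
indazole	c1ccc2[nH]ncc2c1
quinoline	c1ccc2ncccc2c1
isoquinoline	c1ccc2cnccc2c1
quinazoline	c1ccc2ncncc2c1
naphthalene	c1ccc2ccccc2c1
purine	c1nc2[nH]cnc2cn1
pteridine	c1cnc2ncncc2n1
aziridine	C1CN1
azetidine	C1CNC1
pyrrolidine	C1CCNC1
piperidine	C1CCNCC1
piperazine	C1CNCCN1
morpholine	C1COCCN1
thiomorpholine	C1CSCCN1
azepane	C1CCCNCC1
cyclopropane	C1CC1
cyclobutane	C1CCC1
cyclopentane	C1CCCC1
cyclohexane	C1CCCCC1
spiro_atom	[X4;R2](@[*])(@[*])(@[*])@[*]
ring_fusion_atom	[R2]
three_rings	[R]~[R]~[R]~[R]
biaryl	c-!@c
benzyl	c[CH2]
styrene_like	c[CX3]=[CX3]
two_nitrogens	[#7].[#7]
three_nitrogens	[#7].[#7].[#7]
two_oxygens	[#8].[#8]
three_oxygens	[#8].[#8].[#8]
n_and_o	[#7].[#8]
halogen_any	[F,Cl,Br,I]
heavy_halogen	[Br,I]
basic_nitrogen	[NX3;H2,H1,H0;!$(N=*);!$(N[a]);!$(N[C,S,P]=[O,S,N])]
hbond_donor	[#7H,#8H]
hbond_acceptor	[#7X2,#8X2,#8X1]
zwitter_carboxylate_amine	[NX3,NX4+].[CX3](=[OX1])[OX1-,OX2H]
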