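# Tryptophan biosynthesis pathway (chorismate -> L-tryptophan), ordered.
# SMILES pin explicit protonation states (MetaCyc-style charged species at
# physiological pH: carboxylates and phosphate dianions; indole and
# L-tryptophan neutral). Indole is channeled between the alpha and beta
# subunits of tryptophan synthase and cannot diffuse freely.
# CdRP is pinned as the trianion (its fragment TPSA matches the charged
# species; some printed MW values for this compound instead correspond to
# the neutral monoisotopic mass).
name	smiles	position	channeled	note
Chorismate	C(=C)(OC1C=CC(=CC1O)C(=O)[O-])C(=O)[O-]	1	False	dicarboxylate
Anthranilate	Nc1ccccc1C(=O)[O-]	2	False	carboxylate
N-(5-phosphoribosyl)-anthranilate	[O-]C(=O)c1ccccc1NC1OC(COP(=O)([O-])[O-])C(O)C1O	3	False	carboxylate + phosphate dianion
1-(o-carboxyphenylamino)-1-deoxyribulose-5-P	[O-]C(=O)c1ccccc1NCC(=O)C(O)C(O)COP(=O)([O-])[O-]	4	False	carboxylate + phosphate dianion
(1S,2R)-1-C-(indol-3-yl)glycerol 3-phosphate	OC(c1c[nH]c2ccccc12)C(O)COP(=O)([O-])[O-]	5	False	phosphate dianion
Indole	c1ccc2c(c1)cc[nH]2	6	True	channeled within tryptophan synthase
L-tryptophan	N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O	7	False	neutral form
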