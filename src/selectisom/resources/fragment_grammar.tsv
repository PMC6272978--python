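# fragment grammar, version 2
# kind<TAB>name<TAB>smiles (ring1 templates carry {link},{s1},{s2} slots; ring2 carries {d})
ring1	benzene	c1c({s1})cc({link})cc1{s2}
ring1	cyclohexane	C1C({s1})CC({link})CC1{s2}
ring1	pyridine	c1nc({s1})cc({link})c1{s2}
ring1	furan	c1oc({s1})c({link})c1{s2}
ring1	thiophene	c1sc({s1})c({link})c1{s2}
ring2	benzene	c2ccc({d})cc2
ring2	cyclohexane	C2CCC({d})CC2
linker	amide	C(=O)N
linker	ester	C(=O)O
linker	carbamate	OC(=O)N
decoration	none	
decoration	methyl	C
decoration	ethyl	CC
decoration	methoxy	OC
decoration	hydroxyl	O
signature	nitrile	C#N
signature	thioether	SC
signature	chloro	Cl
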