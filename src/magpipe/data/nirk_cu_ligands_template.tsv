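# Template residue map for copper nitrite reductase (NirK) Cu ligands.
# SYNTHETIC TEMPLATE: the positions below are placeholders for the
# Alcaligenes-faecalis-style numbering and MUST be replaced with the
# ungapped coordinates of the actual reference sequence in your
# alignment before use.  Expected residues are the canonical ligands:
# type 1 Cu: His, Cys, His, Met; type 2 Cu: His, His, His.
ref_id	pos	expected	label
REFERENCE	95	H	type1_Cu_His1
REFERENCE	100	H	type2_Cu_His1
REFERENCE	135	H	type2_Cu_His2
REFERENCE	136	C	type1_Cu_Cys
REFERENCE	145	H	type1_Cu_His2
REFERENCE	150	M	type1_Cu_Met
REFERENCE	306	H	type2_Cu_His3
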