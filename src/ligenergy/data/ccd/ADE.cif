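# Minimal component-dictionary-style template for adenine (ADE).
# Hand-written from standard purine chemistry; aromatic ring bonds are
# encoded as AROM and the exocyclic amine as a single bond.
data_ADE
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
_chem_comp_atom.charge
ADE N9 N 0
ADE C8 C 0
ADE N7 N 0
ADE C5 C 0
ADE C6 C 0
ADE N6 N 0
ADE N1 N 0
ADE C2 C 0
ADE N3 N 0
ADE C4 C 0
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
ADE N9 C8 AROM
ADE C8 N7 AROM
ADE N7 C5 AROM
ADE C5 C4 AROM
ADE C4 N9 AROM
ADE C5 C6 AROM
ADE C6 N1 AROM
ADE N1 C2 AROM
ADE C2 N3 AROM
ADE N3 C4 AROM
ADE C6 N6 SING
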