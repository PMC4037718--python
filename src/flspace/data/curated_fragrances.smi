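# Curated classic fragrance molecules and named non-FL exclusions.
# Two columns: SMILES name.
CC1OC(C)=C(O)C1=O furaneol
CC(C)CCOC(C)=O isoamyl_acetate
CCCCCCCC(=O)O caprylic_acid
COc1cc(C=O)ccc1O vanillin
O=C/C=C/c1ccccc1 cinnamaldehyde
CC(=C)C1CCC(C)=CC1 limonene
CC1=CCC2CC1C2(C)C alpha_pinene
CC1(C)C2CCC1(C)C(=O)C2 camphor
CC1CCC(C(C)C)C(=O)C1 menthone
CC1CCOC(C=C(C)C)C1 rose_oxide
CC1CCC(C(C)C)C(O)C1 menthol
CC(CCO)CCC=C(C)C citronellol
CCCCCCCCCCCC=O lauraldehyde
CC(=C)[C@@H]1CC(C)=CC(=O)C1 carvone_minus
CC(=C)[C@H]1CC(C)=CC(=O)C1 carvone_plus
c1cnccn1 pyrazine
CCOC(=O)c1ccccc1N ethyl_anthranilate
CCc1cccnc1 3-ethylpyridine
SC1CCCC1 cyclopentanethiol
CSSC dimethyl_disulfide
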