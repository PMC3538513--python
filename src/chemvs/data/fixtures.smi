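# packaged molecule fixtures: SMILES <whitespace> name
C methane
CC ethane
CCC propane
CCCC butane
CC(C)C isobutane
C1CCCCC1 cyclohexane
CCO ethanol
CC(=O)O acetic_acid
CC(C)=O acetone
CCN ethylamine
CCS ethanethiol
CC#C propyne
CS(C)=O dmso
c1ccccc1 benzene
Cc1ccccc1 toluene
Oc1ccccc1 phenol
Nc1ccccc1 aniline
c1ccncc1 pyridine
c1cc[nH]c1 pyrrole
c1ccoc1 furan
c1ccsc1 thiophene
c1c[nH]cn1 imidazole
c1ccc2ccccc2c1 naphthalene
c1ccc2ncccc2c1 quinoline
NC(=O)c1ccccc1 benzamide
O=[N+]([O-])c1ccccc1 nitrobenzene
CC(=O)Oc1ccccc1C(=O)O aspirin
Cn1cnc2c1c(=O)n(C)c(=O)n2C caffeine
c1ccc(Nc2ncnc3ccccc23)cc1 anilinoquinazoline
C[N+](C)(C)CCOC(C)=O acetylcholine
CC(=O)[O-] acetate
C[Se]C dimethylselenide
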