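name	descriptor	value
methane	nC	1
methane	nN	0
methane	nO	0
methane	nHeavy	1
methane	nRings	0
methane	nBondsHeavy	0
ethane	nC	2
ethane	nN	0
ethane	nO	0
ethane	nHeavy	2
ethane	nRings	0
ethane	nBondsHeavy	1
ethane	Wiener	1
propane	nC	3
propane	nN	0
propane	nO	0
propane	nHeavy	3
propane	nRings	0
propane	nBondsHeavy	2
propane	Wiener	4
propane	Kappa1	3.0
butane	nC	4
butane	nN	0
butane	nO	0
butane	nHeavy	4
butane	nRings	0
butane	nBondsHeavy	3
butane	Wiener	10
isobutane	nC	4
isobutane	nN	0
isobutane	nO	0
isobutane	nHeavy	4
isobutane	nRings	0
isobutane	nBondsHeavy	3
isobutane	Wiener	9
cyclohexane	nC	6
cyclohexane	nN	0
cyclohexane	nO	0
cyclohexane	nHeavy	6
cyclohexane	nRings	1
cyclohexane	nBondsHeavy	6
cyclohexane	Wiener	27
ethanol	nC	2
ethanol	nN	0
ethanol	nO	1
ethanol	nHeavy	3
ethanol	nRings	0
ethanol	nHBDonors	1
ethanol	Wiener	4
ethanol	MW	46.069
ethanol	SsOH	7.569444
acetic_acid	nC	2
acetic_acid	nN	0
acetic_acid	nO	2
acetic_acid	nHeavy	4
acetic_acid	nRings	0
acetic_acid	nHBDonors	1
acetic_acid	Wiener	9
acetone	nC	3
acetone	nN	0
acetone	nO	1
acetone	nHeavy	4
acetone	nRings	0
acetone	nHBAcceptors	1
acetone	Wiener	9
ethylamine	nC	2
ethylamine	nN	1
ethylamine	nO	0
ethylamine	nHeavy	3
ethylamine	nRings	0
ethylamine	nHBDonors	1
ethylamine	Wiener	4
ethanethiol	nC	2
ethanethiol	nN	0
ethanethiol	nO	0
ethanethiol	nS	1
ethanethiol	nHeavy	3
ethanethiol	nRings	0
ethanethiol	Wiener	4
propyne	nC	3
propyne	nN	0
propyne	nO	0
propyne	nHeavy	3
propyne	nRings	0
propyne	nBondsHeavy	2
propyne	Wiener	4
dmso	nC	2
dmso	nN	0
dmso	nO	1
dmso	nS	1
dmso	nHeavy	4
dmso	nRings	0
benzene	nC	6
benzene	nN	0
benzene	nO	0
benzene	nHeavy	6
benzene	nRings	1
benzene	nAromRing6	1
benzene	Wiener	27
toluene	nC	7
toluene	nN	0
toluene	nO	0
toluene	nHeavy	7
toluene	nRings	1
toluene	nBondsHeavy	7
phenol	nC	6
phenol	nN	0
phenol	nO	1
phenol	nHeavy	7
phenol	nRings	1
phenol	nHBDonors	1
aniline	nC	6
aniline	nN	1
aniline	nO	0
aniline	nHeavy	7
aniline	nRings	1
aniline	nHBDonors	1
pyridine	nC	5
pyridine	nN	1
pyridine	nO	0
pyridine	nHeavy	6
pyridine	nRings	1
pyridine	nRingN	1
pyridine	nAromRing6	1
pyrrole	nC	4
pyrrole	nN	1
pyrrole	nO	0
pyrrole	nHeavy	5
pyrrole	nRings	1
pyrrole	nRingN	1
pyrrole	nAromRing5	1
pyrrole	nHBDonors	1
furan	nC	4
furan	nN	0
furan	nO	1
furan	nHeavy	5
furan	nRings	1
furan	nRingO	1
furan	nAromRing5	1
thiophene	nC	4
thiophene	nN	0
thiophene	nO	0
thiophene	nS	1
thiophene	nHeavy	5
thiophene	nRings	1
thiophene	nRingS	1
thiophene	nAromRing5	1
imidazole	nC	3
imidazole	nN	2
imidazole	nO	0
imidazole	nHeavy	5
imidazole	nRings	1
imidazole	nRingN	1
imidazole	nAromRing5	1
naphthalene	nC	10
naphthalene	nN	0
naphthalene	nO	0
naphthalene	nHeavy	10
naphthalene	nRings	2
naphthalene	nBondsHeavy	11
naphthalene	nAromRing6	2
quinoline	nC	9
quinoline	nN	1
quinoline	nO	0
quinoline	nHeavy	10
quinoline	nRings	2
quinoline	nBondsHeavy	11
quinoline	nRingN	1
benzamide	nC	7
benzamide	nN	1
benzamide	nO	1
benzamide	nHeavy	9
benzamide	nRings	1
benzamide	nHBDonors	1
benzamide	nRotatable	1
nitrobenzene	nC	6
nitrobenzene	nN	1
nitrobenzene	nO	2
nitrobenzene	nHeavy	9
nitrobenzene	nRings	1
nitrobenzene	nBondsHeavy	9
aspirin	nC	9
aspirin	nN	0
aspirin	nO	4
aspirin	nHeavy	13
aspirin	nRings	1
aspirin	nHBDonors	1
aspirin	nBondsHeavy	13
caffeine	nC	8
caffeine	nN	4
caffeine	nO	2
caffeine	nHeavy	14
caffeine	nRings	2
caffeine	nBondsHeavy	15
anilinoquinazoline	nC	14
anilinoquinazoline	nN	3
anilinoquinazoline	nO	0
anilinoquinazoline	nHeavy	17
anilinoquinazoline	nRings	3
anilinoquinazoline	nHBDonors	1
anilinoquinazoline	nBondsHeavy	19
acetylcholine	nC	7
acetylcholine	nN	1
acetylcholine	nO	2
acetylcholine	nHeavy	10
acetylcholine	nRings	0
acetylcholine	nHBDonors	0
acetylcholine	nHBAcceptors	2
acetylcholine	nBondsHeavy	9
acetate	nC	2
acetate	nN	0
acetate	nO	2
acetate	nHeavy	4
acetate	nRings	0
acetate	nHBDonors	0
acetate	nHBAcceptors	2
dimethylselenide	nC	2
dimethylselenide	nN	0
dimethylselenide	nO	0
dimethylselenide	nHeavy	3
dimethylselenide	nRings	0
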