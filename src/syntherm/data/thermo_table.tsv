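# Standard Gibbs energies and enthalpies of formation at 298.15 K, 1 M / 1 atm
# standard states (aqueous solutes vs 1 M, gases vs 1 atm, liquid water a=1).
# Convention of Thauer, Jungermann & Decker 1977 (Bacteriol Rev 41:100-180),
# with CH4(g) at the one-decimal rounding -50.8 kJ/mol used throughout the
# syntrophy literature; enthalpies from the NBS tables (Wagman et al. 1982).
# table_version: 1
name	phase	formula	charge	dgf0_kj_mol	dhf0_kj_mol	source
propionate	aqueous	C3H5O2	-1	-361.08	-510.80	Thauer1977/NBS82
acetate	aqueous	C2H3O2	-1	-369.41	-486.01	Thauer1977/NBS82
formate	aqueous	CHO2	-1	-351.00	-425.55	Thauer1977/NBS82
bicarbonate	aqueous	CHO3	-1	-586.85	-691.99	NBS82
H+	aqueous	H	1	0.00	0.00	convention
H2O	water	H2O	0	-237.17	-285.83	Thauer1977/NBS82
H2	gas	H2	0	0.00	0.00	convention
CO2	gas	CO2	0	-394.36	-393.51	Thauer1977/NBS82
CH4	gas	CH4	0	-50.80	-74.81	Thauer1977-rounded/NBS82
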