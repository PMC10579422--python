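# Henry solubility constants at 298.15 K (mol L-1 atm-1) with van't Hoff
# temperature slopes d(ln kH)/d(1/T) in K, compiled from Sander 2015
# (Atmos Chem Phys 15:4399-4981). kH(T) = kh_298 * exp(slope*(1/T - 1/298.15)).
name	kh_298_mol_l_atm	vant_hoff_K	source
H2	7.8e-4	500	Sander2015
CH4	1.4e-3	1700	Sander2015
CO2	3.4e-2	2400	Sander2015
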