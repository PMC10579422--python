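# Default batch scenario: a fast propionate-degrading assay (serum bottle,
# undiluted thermophilic high-ammonia enrichment culture, 52 degC, pH 8.5).
# Guild parameters are illustrative values calibrated once to the qualitative
# behaviour of such assays (propionate depleted within ~25 days, transient
# acetate accumulation of 2-3 g/L, hydrogen partial pressure a few Pa) and
# then frozen; they are not estimates for any particular organism.
name = "b01_like"

[conditions]
temperature_K = 325.15
ph = 8.5
liquid_volume_L = 0.5
headspace_ratio = 1.0     # headspace:liquid volume ratio

[initial]
propionate_mM = 37.0
acetate_mM = 4.0
formate_mM = 0.1
h2_pa = 1.0
co2_atm = 0.30
ch4_atm = 1e-4
biomass_spo_g_L = 0.02
biomass_sao_g_L = 0.005
biomass_hm_g_L = 0.03

[spo]
vmax = 0.038      # mol propionate (g biomass)^-1 day^-1
ks = 1.0e-3       # mol/L
yield_g_per_mol = 2.5
decay = 0.01      # day^-1
dg_min = 10.0     # kJ per reaction; thermodynamic limitation offset

[sao]
vmax = 0.055      # mol acetate (g biomass)^-1 day^-1
ks = 1.5e-2
yield_g_per_mol = 2.2
decay = 0.01
dg_min = 3.0      # acetate oxidisers operate at the thermodynamic margin

[hm]
vmax = 1.2        # mol H2 (g biomass)^-1 day^-1
ks = 6.0e-8       # mol/L dissolved H2
yield_g_per_mol = 0.3
decay = 0.01
dg_min = 12.0     # ~1/4 ATP equivalent per CH4

[observation]
t_end_days = 100.0
interval_days = 1.0
noise_cv = 0.05
seed = 12021
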