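"""In-situ guild energies and the per-propionate energy partition.

Evaluates ΔG = ΔG°(T) + RT ln Q for each guild at a measured batch state
(52 °C, pH 8.5, 30 mM propionate, 40 mM acetate, 8 Pa H2) and distributes
the available energy per mole of propionate mineralised with the
stoichiometric weights (1, 1, 1.75).
"""

from syntherm import ATM_PA, ThermodynamicState, guild_energies, overall_delta_g

state = ThermodynamicState(
    temperature=325.15,
    ph=8.5,
    solutes={"propionate": 0.030, "acetate": 0.040},
    gases={"H2": 8.0, "CO2": 0.3 * ATM_PA, "CH4": 0.5 * ATM_PA},
)

report = guild_energies(state, carrier="hydrogen")
print(report.to_frame().to_string(index=False, float_format=lambda x: f"{x:8.2f}"))
print(f"\ntotal per mol propionate : {report.total:8.2f} kJ")
print(f"overall-scheme oracle    : {overall_delta_g(state):8.2f} kJ")

print(
    "\nEach guild clears only -10..-30 kJ per reaction, but because 1.75 mol"
    "\nCH4 form per mol propionate the methanogen collects the largest share"
    "\nof the ~-100 kJ total; the guild sum matches the overall scheme exactly"
    "\nbecause the intermediates cancel."
)
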