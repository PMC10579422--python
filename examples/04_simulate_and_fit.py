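"""Simulate a batch assay, add measurement noise, recover the kinetics.

Runs the packaged default scenario (37 mM propionate pulse into a
thermophilic high-ammonia culture), overlays 5% multiplicative measurement
noise, then estimates the methane-phase specific rate, doubling time,
peak volumetric degradation rate and methane yield — the same quantities a
batch experiment reports.
"""

from syntherm import (
    SimulationScenario,
    fit_kinetics,
    methane_yield,
    observe,
    simulate,
    volumetric_rate,
)

scenario = SimulationScenario.default()
clean = simulate(scenario)
noisy = observe(clean, cv=scenario.noise_cv, seed=scenario.seed)

prop = clean.channels["propionate"]
print(f"propionate: {prop[0]:.1f} -> {prop[-1]:.2f} mM over {clean.time[-1]:.0f} days")
print(f"acetate transient peak  : {clean.channels['acetate'].max() * 59.04 / 1000:.2f} g/L")
print(f"H2 range (active phase) : {clean.channels['h2'][2:25].min():.1f}"
      f"-{clean.channels['h2'][2:25].max():.1f} Pa")

report = fit_kinetics(noisy, "ch4", min_points=5)
print(f"\nmu(CH4)      = {report.mu:.3f} 1/day  (window days "
      f"{noisy.time[report.window[0]]:.0f}-{noisy.time[report.window[1] - 1]:.0f}, "
      f"R^2 = {report.r_squared:.3f})")
print(f"doubling time = {report.doubling_time:.1f} days")
print(f"peak rate     = {volumetric_rate(clean, 'propionate', 5.0):.3f} g/L/day "
      f"(noisy series: {volumetric_rate(noisy, 'propionate', 5.0):.3f})")
y = methane_yield(clean, "propionate")
print(f"CH4 yield     = {y.yield_mol_per_mol:.3f} mol/mol "
      f"(theoretical {y.theoretical})")

print(
    "\nThe noiseless run closes the books: ~1.75 CH4 per propionate, a peak"
    "\ndegradation rate of ~0.2 g/L/day and hydrogen pinned at a few Pa by"
    "\nthe methanogen - the signature of a healthy dual syntrophy. Note how"
    "\n5% measurement noise inflates the max-over-windows volumetric rate;"
    "\nwiden window_days to tame it on real data."
)
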