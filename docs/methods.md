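# Methods

`syntherm` analyses the energetics and kinetics of the *dual syntrophy* that
mineralises propionate in thermophilic, high-ammonia anaerobic digesters:
syntrophic propionate-oxidising bacteria (SPOB) convert propionate to
acetate, CO₂ and H₂; syntrophic acetate-oxidising bacteria (SAOB) convert the
acetate to CO₂ and H₂; hydrogenotrophic methanogens (HM) sink the electrons
as CH₄. This note records the models, conventions and numerical choices, and
what the synthetic-data generator does and does not emulate.

## Thermodynamic model

**Reactions.** The packaged guild reactions (hydrogen carrier) are

| guild | reaction | ΔG° (298.15 K) |
|---|---|---|
| SPO | propionate⁻ + 2 H₂O → acetate⁻ + CO₂ + 3 H₂ | +71.65 kJ |
| SAO | acetate⁻ + H⁺ + 2 H₂O → 2 CO₂ + 4 H₂ | +55.03 kJ |
| HM | 4 H₂ + CO₂ → CH₄ + 2 H₂O | −130.78 kJ |

with CO₂, CH₄ and H₂ as gases. Summing SPO + SAO + 1.75 × HM cancels all
intermediates (3 + 4 = 7 H₂ = 1.75 × 4) and gives the overall mineralisation
propionate⁻ + H⁺ + ½ H₂O → 1.75 CH₄ + 1.25 CO₂ (−102.19 kJ). Formate-carrier
variants (each n H₂ replaced by n formate⁻ + n H⁺ − n CO₂) and a
bicarbonate-referenced set are provided; the gaseous-CO₂, hydrogen-carrier
set is the default because the guild equations are conventionally written
that way. A widely circulated misprint of the acetate-oxidation equation
writes the products as 2 CO₂ + 4 H₂O; `validate_reaction` flags that form as
oxygen-unbalanced (hydrogen happens to balance), and the corrected 4 H₂ form
is what ships.

**Formation table.** Standard formation energies follow the Thauer
convention (acetate⁻ −369.41, propionate⁻ −361.08, formate⁻ −351.0, CO₂(g)
−394.36, H₂O(l) −237.17 kJ mol⁻¹; H₂ and H⁺ zero), with CH₄(g) at the
one-decimal rounding −50.8 kJ mol⁻¹ used throughout the syntrophy
literature; this combination reproduces the three literature ΔG° values
(+55.0, −130.8, −75.8 kJ) to better than 0.05 kJ. Enthalpies are NBS values.
The table ships as a versioned TSV; user tables in the same dialect can be
substituted everywhere.

**Activities.** Aqueous solutes count against 1 M, gases against 1 atm
(inputs in Pa, 101325 Pa atm⁻¹), water at unit activity, H⁺ as 10^−pH.
Ionic-strength/activity-coefficient corrections (Davies, Pitzer) are out of
scope: digester liquors are concentrated and a credible correction would
need an electrolyte model the input data cannot constrain. In-situ values
are therefore concentration-based ΔG, the convention under which the
literature band of −10…−30 kJ per reaction is quoted.

**Temperature.** ΔG°(T) = (T/T°)·ΔG°(T°) + (1 − T/T°)·ΔH°(T°)
(Gibbs–Helmholtz with temperature-independent ΔH°), valid for the
273–373 K liquid-water range; heat-capacity corrections are omitted as they
shift the guild reactions by well under 1 kJ across that span.

## Energy partition

Per mole of propionate mineralised the guild reactions run with weights
(1, 1, 1.75), so the per-guild energy shares are (ΔG_SPO, ΔG_SAO,
1.75·ΔG_HM). Their sum equals ΔG of the overall scheme at the same state —
an exact linear identity used as a property test (1 × 10⁻⁶ kJ over
randomised admissible states). Energies are reported per mole of reaction
without ATP-equivalent or dissipation corrections. Both electron carriers
are supported; at H₂/CO₂/formate interconversion equilibrium
(`carrier_equilibrium_check` → 0) the two partitions coincide guild by guild.

## Hydrogen window

With every activity except H₂ fixed, ΔG is linear in ln pH₂ with slope
n·R·T (n = the reaction's H₂ coefficient). The window in which an
H₂-producing guild and the H₂-consuming methanogen both clear a threshold
ΔG* is closed-form: upper = exp((ΔG* − A_p)/(n_p·R·T)), lower =
exp((A_c − ΔG*)/(|n_c|·R·T)) (in atm, A = ΔG at 1 atm H₂), converted to Pa.
Default thresholds are 0 and −10 kJ, both always reported. Endpoints are
verified against Brent root-finding on the full ΔG expression to 1 × 10⁻⁶
relative. Co-varying CO₂ with H₂ is outside the closed form; use the numeric
route for that.

## Kinetics

Specific rates are OLS slopes of ln(value) against time over a detected
exponential window; doubling time is ln 2/µ. The window is the contiguous
stretch of ≥ `min_points` (default 4) strictly positive values maximising
fit R², ties broken toward the longer then the earlier window. Two
deliberate choices: a zero-variance (flat) window scores R² = 0, not 1, so
plateaus cannot outcompete the growth phase (a genuinely constant series
still returns the full window via the tie rule); and because short windows
of noisy data can reach high R² by chance, the window is always reported
next to the estimate rather than hidden — on noisy series prefer a larger
`min_points` or an explicit window. Methane yield is ΔCH₄/Δacid in mole
units (theoretical 1.75 for propionate, 1.0 for acetate), assuming the
cumulative CH₄ channel shares the per-litre-of-liquid basis of the acid
channels. Volumetric rates take the maximum of Δc/Δt over all point pairs
no further apart than `window_days` (default 5 d), converted with anion
molar masses (propionate 73.07, acetate 59.04 g mol⁻¹, matching mM
reporting of fully dissociated acids at digester pH).

## Speciation

Free ammonia uses the Anthonisen-form fraction
10^pH/(exp(6344/T) + 10^pH) applied to total ammonia nitrogen; results are
reported on both the g N L⁻¹ and g NH₃ L⁻¹ bases because field reports are
ambiguous about theirs, and no claim is made as to which basis any given
literature figure uses. VFA anion fractions are Henderson–Hasselbalch with
CRC pKa values. Gas–liquid conversion uses Henry constants at 298.15 K with
van't Hoff slopes (Sander compilation): kH(T) = kH°·exp(s·(1/T − 1/298.15)).

## Batch simulator (synthetic-data generator)

The generator emulates the serum-bottle assays these communities are
studied in: 0.5 L of undiluted enrichment culture plus an equal headspace,
52 °C, pH 8.5, a 37 mM propionate pulse (the reported assay range is
21–37 mM) on a small acetate background, observed daily for 100 days with
5% multiplicative lognormal measurement noise (seeded; pH and temperature
are regulated quantities and stay noiseless; the cumulative CH₄ channel is
re-monotonised with a running maximum).

**Model.** Each guild's rate is v_max·X·S/(K_S + S)·F_T with
F_T = max(0, 1 − exp((ΔG + ΔG_min)/(R·T))) and ΔG evaluated from the
packaged table at the instantaneous state, so the kinetics stall exactly
where thermodynamics says they must (tested as a "second law" invariant at
every stored step). H₂, CO₂ and CH₄ partition instantaneously between
liquid and headspace by Henry equilibrium (no k_La mass-transfer
resistance — the assays report no such data); HM's Monod substrate is
dissolved H₂. pH is clamped (bicarbonate buffer); the carbonate system is
not titrated. Biomass (CH₁.₈O₀.₅N₀.₂, 24.63 g per mol C) draws its carbon
from the CO₂ pool and decay returns it there, so total carbon closes
exactly while the catabolic stoichiometry — and hence the 1.75 CH₄ per
propionate — is untouched.

**Integration.** The dissolved-plus-headspace H₂ pool at a few Pa is
~10⁻⁶ mol against fluxes of ~10⁻² mol d⁻¹: the pool relaxes in seconds and
the ODE system is stiff. Integration therefore uses LSODA
(`scipy.integrate.solve_ivp`, rtol 10⁻⁸, per-state atol down to 10⁻¹⁶ for
the gas pools) rather than an explicit fixed-step scheme, which would need
~10⁵–10⁶ steps for stability. The solver is deterministic: identical
scenario and seed reproduce the series bit-for-bit.

**Defaults and their rationale.** Guild parameters are illustrative, not
estimates of the study organisms; they were calibrated once against the
qualitative physiology of a fast propionate-degrading thermophilic batch —
propionate depleted between day 20 and 30, a transient acetate accumulation
of 2–3 g L⁻¹ before acetate oxidation takes over, H₂ within ~3–12 Pa during
active degradation, SPO energy around −20 kJ, peak degradation rate of
order 0.1–0.2 g L⁻¹ d⁻¹, methane yield within 2% of 1.75 — and then frozen
in `data/scenario_default.toml`. The minimum energy quanta are per guild:
SPO 10 kJ, SAO 3 kJ, HM 12 kJ. A uniform 10 kJ would deadlock the serial
SAO→HM chain at ~17 mM acetate in a sealed bottle (once headspace CH₄ and
CO₂ accumulate, barely 15 kJ per acetate remains to split), which
contradicts the near-complete acetate consumption these cultures show;
acetate oxidisers are the guild known to live closest to the thermodynamic
margin, and ~12 kJ is about a quarter ATP equivalent for the methanogen.

**What passing tests do and do not show.** The generator reproduces the
*structure* of real assays — sequential SPO→SAO phases emerging from
thermodynamic gating alone, a self-regulating H₂ set point, mass- and
electron-balanced channels, realistic noise. It does not emulate ammonia
inhibition dynamics, lag phases, mass-transfer limitation, pH drift,
headspace sampling/venting, formate as a dynamic pool (the formate channel
is an inert residual), or between-replicate biological variability. Tests
passing on synthetic data therefore validate the analysis pipeline's
correctness and calibration-range behaviour, not parameter estimates for
any real community.

## Pipeline and I/O

Time series travel as tidy CSV (`time_d, channel, value, unit`) with a
fixed unit registry (mM for acids and cumulative CH₄, Pa for gases, K for
temperature); unknown units and duplicated (time, channel) pairs are
rejected, out-of-order times are sorted with a warning. Configuration and
scenarios are TOML. Reports are emitted as JSON at full precision and TSV
at 4 significant digits so text outputs are byte-stable; reruns on the same
inputs are byte-identical. If an input series lacks gas channels the ΔG
stages are skipped per assay with a warning (kinetics still run); when only
H₂ is present, configurable default CO₂ (0.3 atm) and CH₄ (0.5 atm)
headspace pressures complete the state. Exit codes: 0 ok, 2 validation
error, 3 computation error.

## Known limitations

- No electrolyte activity model; ΔG values are concentration-based.
- The hydrogen window treats all non-H₂ activities as fixed.
- Exponential-window detection is heuristic on noisy data; inspect the
  reported window and R².
- The simulator's sealed-bottle pressure build-up is idealised (no venting),
  which is precisely why its late-stage thermodynamics pinch harder than in
  sampled laboratory bottles.
- Doubling times from product-formation curves reflect community activity,
  not necessarily the growth rate of any single organism.
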