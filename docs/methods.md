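# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, what the synthetic forcing does and does not
emulate, the numerical choices, and the known limitations.

## Life-cycle model

An individual passes through six phases tied to lipid dynamics:

1. **Non-feeding egg/nauplius.** A pure timer: duration
   `7 · 2^((10−T)/10)` days (7 d at 10 °C, Q10 = 2 using the SST of the
   spawn day), rounded up to whole days for the daily time step. No
   metabolic loss is charged in this phase (yolk maintenance is ignored).
2. **Feeding and structural growth** to a critical structure of 3 μmol C.
3. **Growth plus lipid deposition** until structure ≥ 6.5 μmol C and lipid
   ≥ 7.52 μmol C (total 14.0 μmol C, the diapause-entry criterion; the
   lipid threshold is 80% of an original 9.4 μmol C criterion). Positive
   net carbon is split half/half between structure and lipid until the
   structural target is met, then goes entirely to lipid.
4. **Diapause** in deep water at a constant 4 °C, metabolism suppressed by
   a factor 0.01, fuelled by lipid.
5. **Gonad development**: 14 days in deep water, lipid respired at the
   full (unsuppressed) basal rate times `gonad_metab_factor` (default 1).
   The individual enters this phase exactly 14 days before its realized
   exit day; transitions between surface and depth are instantaneous.
6. **Income-breeding adult** at the surface from the exit day onward:
   positive net carbon is converted to eggs (floor of net/egg_carbon, the
   remainder carried to the next day), negative net carbon draws down the
   remaining lipid.

Energetics are carbon-only and mass-specific on structural carbon:

- ingestion `I = Imax(T) · S²/(k² + S²)` with `S` the summed concentration
  of the four food resources (diatoms, non-diatoms, microzooplankton,
  detritus), `Imax` referenced at 10 °C with Q10 = 2, and assimilation
  efficiency 0.7. The maximum specific ingestion (0.45 d⁻¹) and basal
  metabolism (0.06 d⁻¹ on structure, Q10 = 2) give copepods positive
  scope above ≈ 1.2 mmol C m⁻³ of food regardless of temperature (the two
  Q10 values cancel in the break-even point).
- Making ingestion mass-specific (rather than a fixed per-individual
  maximum) keeps early development exponential and development times
  realistic: an egg of 0.023 μmol C cannot ingest a fixed adult-sized
  ration. This is a deliberate simplification of a full stoichiometric
  (C and N) physiology; the module exposes only daily
  phase/biomass/egg records, so a richer core can replace it without
  touching the selection machinery.
- **Starvation** occurs the day reserves are exhausted while the daily
  carbon balance is negative. Developing stages (phase 2) carry no
  reserve, so they starve on their first negative day — this sharply
  defines the viable spawning window and is intended: eggs spawned outside
  the growing season must die of food scarcity.

Life histories are deterministic given (spawn year, spawn day, exit day)
and the forcing, so they are precomputed once over the full grid — 51
spawn bins (days 50–300, 5 apart) × 16 exit days (50–200, 10 apart) × the
number of forcing years — into a lookup store (816 trajectories per year).
An individual whose development cannot reach the diapause threshold before
its scheduled gonad phase is recorded as non-viable (zero fitness), not an
error. Every life cycle spans at most two years.

### Parameter defaults

| parameter | value | units | why |
|---|---|---|---|
| phase1_days_at_10c | 7 | d | development timer reference |
| dev_q10, graz_q10, metab_q10 | 2 | – | standard physiological Q10 |
| graz_imax_ref | 0.45 | d⁻¹ | egg→diapause in ≈ 45 d under bloom food |
| graz_half_sat | 2.5 | mmol C m⁻³ | break-even food ≈ 1.2, near the 2.0 bloom-onset threshold, so adult survival hinges on bloom timing |
| assimilation_efficiency | 0.7 | – | typical for copepods |
| basal_metab_ref | 0.06 | d⁻¹ | realistic mass-specific metabolism; with the lipid left at exit (≈ 4 μmol C) gives a 2–4 week post-exit famine buffer |
| diapause_metab_factor | 0.01 | – | two orders of magnitude suppression |
| structure/lipid at diapause | 6.5 / 7.52 | μmol C | entry criterion (total 14.0) |
| egg_carbon | 0.023 | μmol C | ≈ 0.28 μg C per egg; scales fecundity only — selection depends on relative fitness |
| deep_t | 4 | °C | constant deep-water temperature |
| max_lifespan_days | 730 | d | two-year cap |

## Predation mortality

Daily Bernoulli death with probability `m(T) = m_ref · exp(0.214 (T − 9))`
for surface phases (m₁ = 0.03 d⁻¹ phases 1–3, m₃ = 0.02 d⁻¹ phase 6;
`exp(10·0.214) ≈ 8.5` per 10 °C) and a flat m₂ = 0.002 d⁻¹ in deep water,
never temperature-scaled (deep temperature is constant anyway).
Probabilities are capped at 1 under sensitivity scalings. Eggs and
non-feeding nauplii share m₁; their additional non-predatory losses are
handled separately as starvation. The `flat` sensitivity freezes m₁ and m₃
at their reference values (both, not just m₁); `x1.5`/`x2.0` multiply all
rates.

## Traits and phenotypic variance

The realized exit day of an individual is
`clamp(round₁₀(μ + N(0, SDPV²)), 50, 200)`, drawn once at the egg stage;
rounding is to the nearest multiple of 10 with ties away from zero, and
out-of-range draws are **clamped** to the grid edges rather than redrawn,
keeping every realized day on the trajectory grid. Inheritance is identity
(no mutation, no recombination; all individuals are treated as egg-laying
females).

## Selection engine

Per generation: each egg realizes an exit day, the matching trajectory is
looked up, its stochastic fate (predation day vs deterministic starvation
day vs record end) is sampled, and surviving adults contribute their daily
egg schedule — truncated at their own death day — binned to the nearest
5-day spawn bin (integer days never tie; effective ties round down) with
the parent's trait. Offspring outside bins 50–300 are discarded as
non-viable. Exactly n_pop eggs are passed forward by largest-remainder
proportional resampling (RNG used only to break remainder ties), so cell
frequencies are preserved to within one egg per cell. Convergence is
strict fixation: a single trait cell remaining. After fixation, extra
years (default 10, one full pass of the decade) are simulated with
per-cell records for the diagnostic analyses.

Sampling is performed cohort-wise: individuals sharing (trait, bin, exit)
are exchangeable, so realized exits are drawn multinomially from the
discretized Gaussian, per-phase fates multinomially from the exact
per-trajectory fate probabilities, and adult death days multinomially from
the conditional death-day distribution. These cohort laws are *identical*
to independent per-individual daily Bernoulli draws (verified against a
brute-force oracle by Kolmogorov–Smirnov test at n = 10⁵), while making
the cost of a generation independent of population size. RNG is consumed
in a fixed canonical cell order, so a run is a pure function of its seed.

Because every viable trajectory exits diapause the year after spawning and
viable spawn dates are confined to days 50–300, each generation advances
the forcing-year index by exactly one, wrapping around the decade.

### The expected-fitness oracle

An independent deterministic check: for each trait, the expected offspring
matrix over spawn bins (survival probability × egg schedule, weighted by
the trait's realized-exit mass) is built per forcing year, and fitness is
the dominant eigenvalue of the year-cycle product, to the power 1/n_years
— the long-run eggs-per-egg growth factor. The stochastic engine's
converged trait is required to match this argmax on repeat-year scenarios.

At very small sub-populations (2 eggs per cell) convergence can settle one
grid step later than the expected-fitness argmax in low-fitness scenarios:
strategies with slightly lower mean but lower variance of reproductive
success are favoured when absolute numbers are small (the classical
variance discount of fitness in finite populations). The oracle-equivalence
test therefore uses a high-fitness (early-bloom) scenario where the effect
is absent; the full-scale runs do not exhibit it.

## Synthetic forcing

One year is a Gaussian pulse of total food over a 0.3 mmol C m⁻³ winter
baseline, partitioned by fixed fractions (0.45/0.30/0.15/0.10), plus a
sinusoidal SST cycle (default 3.5–14 °C, peak day 225; growing-season mean
≈ 9 °C). A year is configured by its bloom onset day (first crossing of
2 mmol C m⁻³), peak day, and peak concentration; the pulse width follows
from onset and peak. Days are 1-based Julian days; years are 365 days.

The decade preset holds ten such years: bloom peak days span exactly
140 (year 4, earliest) to 170 (year 2, latest); years 7 and 9 are
early-onset years with large slow-building blooms (onsets days 85 and 90);
years 1, 2, 3, 6, 10 have colder springs; year 2 is the anomalous year —
cold spring (2 °C spring anomaly) with bloom onset at day 144, roughly a
month later than a typical year, and a sharp high-amplitude pulse.
Onset days deliberately span about two months (85–144) even though peak
days span only one: single-year optima then range over days 80–140, and it
is this onset spread — not the peak spread — that makes interannual
variability consequential enough for bet-hedging variance to be selected.
The half-saturation choice (break-even food near the onset threshold) has
the same purpose: it ties both adult survival and egg viability to bloom
timing rather than to the long Gaussian tails.

What the generator does **not** emulate: multi-scale weather noise within
years, bloom shape asymmetry, advection of water parcels past a fixed
station, correlated food-component dynamics, or leap years. Passing tests
therefore demonstrate the selection machinery and the qualitative ecology
(onset tracking, bet-hedging, predation-regime response), not quantitative
prediction for any real station.

## Numerical choices

- Phase-1 duration is rounded up to whole days (daily time step).
- 5-day forcing tables are interpolated linearly to daily.
- Trajectory CSVs round-trip bit-exactly (17 significant digits on write,
  round-trip float parsing on read).
- Largest-remainder resampling is deterministic given the cohort, with
  RNG only for remainder ties.
- Fate probability vectors are renormalized against accumulated float
  drift before multinomial sampling (relative error ≤ 1e-12).
- Starvation during phases 4–5 (possible only under extreme parameters)
  is folded into the "starved in development" fate category.

## Scale and run time

Generation cost scales with the number of occupied trait × bin × exit
cells, not with n_pop, so experiments run at the full population schedule
(408,000 → 100,000 after 20 generations; 2,040,000 → 500,000 for the
high-predation sensitivity). A full interannual run converges in
150–600 generations, a few seconds on one CPU; the 8,160-trajectory decade
store builds in ~4 s. The desk preset (2 eggs per cell, 8,160 eggs) exists
for quick exploration; its plateau guard is 400 generations (600 for
full-scale runs, where the final fixation between near-neutral neighbours
can be drift-limited).

## Known limitations

- No capital breeding, no diel vertical migration, no one-year
  (diapause-skipping) life-cycle variant, no density dependence, no
  explicit sexes or mate limitation, no spatial structure.
- The carbon-only physiology omits nitrogen co-limitation, biomass
  turnover and specific dynamic action; absolute fecundities are
  accordingly about twice the magnitudes a full stoichiometric model
  produces, which rescales fitness without moving trait optima.
- Strict-fixation convergence at large n_pop can stall between exactly
  neutral variants; the plateau guard reports this honestly rather than
  forcing an answer.
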