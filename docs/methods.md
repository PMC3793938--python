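# Methods

## The model

`gramscape` simulates one *average axis* (tiller) of a monospecific sward of
a perennial C3 grass, together with the tiller density of the population, on
a daily time step.  The state comprises three structural compartments
(shoot structure as leaf cohorts plus their sheath share, fine roots,
photosynthetic protein), one labile C–N substrate pool (`W_C`, `W_N`), two
reserve pools, the tiller density, and the cumulative thermal time.  The
substrate mass balances are

    dW_C/dt = Photosynthesis + Remobilisation − Respiration − Partitioning − Storage − Exudation
    dW_N/dt = Uptake + Fixation + Remobilisation − Partitioning − Storage − Exudation

with fixation and exudation fixed at zero for grasses.  Every term is an
explicit daily flux, and the package verifies closed-system C and N ledgers
(plant + litter + harvest, and the mineral soil pool) to 1e-6 relative on
every simulated day.

### Process closures

The daily step applies, in order: management events → light interception →
photosynthesis → N uptake → respiration and growth → substrate balance →
allocation-coefficient relaxation → morphogenesis → tiller demography.

* **Interception** is Beer–Lambert, `f = 1 − exp(−k LAI)`, with the
  extinction coefficient optionally density-dependent (erectness rises with
  tiller density; off by default, exponent `k_dens_exp = 0`).
* **Photosynthesis** is a smooth minimum (quadratic, curvature
  `smooth_theta = 0.95`) of a light-limited limb `eps_light · PAR_int` and a
  capacity limb `amax_protein · W_protein · f(T)`.  The light limb is
  discounted by the canopy-age efficiency (below).
* **N uptake** is Michaelis–Menten in mineral soil N over the plant's root
  area (`umax · SRA_eff · W_root · N/(k_m + N)`), capped so the population
  extracts at most half the pool per day.  Mineral soil N receives a constant
  background mineralisation (0.015 gN m⁻² d⁻¹) and fertiliser pulses, and
  loses a constant daily fraction (2%) to leaching/immobilisation.
* **Growth** follows a supply/demand law with bilinear substrate control,
  `G = g_max f(T) · W_C/(W_C + k_C W) · W_N/(W_N + k_N W) · W`, split
  root : shoot by the coefficient `P` and shoot structure : protein by `Q`.
  Each sink is additionally capped by its morphogenetic capacity (lamina
  extension rate and potential lamina size, maximum root mass, maximum
  protein load per lamina mass).  Maintenance respiration has first call on
  C; growth is scaled by a common factor whenever the pools cannot cover its
  stoichiometric C and N cost, so pools never go negative.
* **Allocation coefficients.** `P` relaxes (time constant 5 d) toward
  `p_ref · (C:N)/(C:N)_target`, clipped to `[p_min, p_max]`: the functional
  balance between root and shoot activity.  `Q` integrates the normalised
  difference between the light- and capacity-limited limbs (time constant
  10 d): the coordination of leaf photosynthesis, whose fixed point is
  co-limitation.  A stoichiometric term (`q_stoich = 0.5`) damps `Q` while
  the substrate C:N ratio sits above its target, so a plant accumulating
  excess C downsizes its photosynthetic machinery until the *acquisition*
  of C and N co-limits rather than fixing C it cannot use.
* **Morphogenesis.**  A new leaf cohort appears at every phyllochron
  crossing; the day's shoot structural growth extends expanding cohorts in
  proportion to their remaining sink; a cohort sheds gradually over the last
  quarter of the leaf lifespan and is removed at `age ≥ LLS`, its mass going
  to litter with 60% of its N and 20% of its C remobilised into the
  substrate pools.  Root tissue turns over on the fine-root lifespan.
  Realised height follows the longest lamina with density-dependent
  erectness, capped at the potential height.
* **Tiller demography.**  Below the critical LAI (species-adapted, see
  below; 5.0 for the default grass), tiller density grows
  logistically toward the potential density `TD0`, at a rate damped by
  substrate sufficiency and canopy closure; above it, self-thinning removes
  tillers exponentially.  The daily update is the exact flow of this ODE
  with coefficients frozen over the day.  New tillers dilute the average
  axis (population mass conserved); dead tillers send their structural and
  protein mass to litter while the substrate pools — shared among
  interconnected tillers — pass to the survivors.
* **Cutting** removes, from every lamina whose tip stands above the residual
  height (default 5 cm), the fraction of its length above the cut, together
  with the corresponding sheath and protein share; removed mass is recorded
  as harvest.  Fertilisation adds its amount to the mineral soil pool.

### Trait mapping

The four manipulated traits enter as simple parameter transformations, so a
trait sweep changes nothing else:

| trait | parameter | mapping |
|---|---|---|
| SLA (cm² g⁻¹) | LDMC | `1 / (SLA · leaf_thickness · 1 g cm⁻³)` |
| H (cm) | potential lamina length `L0` | `H / height_shape_factor` (2.0) |
| LLS (°C·d) | phyllochron | `LLS / n_leaves_alive` (3 live leaves per tiller) |
| TD (m⁻²) | `TD0` | identity (initial and potential tiller density) |

### What shapes the adaptive landscape

Four deliberately simple cost laws create the interior optima and the trait
coordination the landscape analyses quantify.  They are this package's
closures, each standing for a documented piece of grass ecophysiology:

1. **Tissue-economics respiration**: specific maintenance respiration scales
   as `(SLA/SLA_ref)^1.2` — cheap, low-LDMC tissue is metabolically more
   active per dry gram.  Penalises high SLA; favours it through cheaper
   canopy construction and turnover.  Their balance sets the SLA optimum and,
   because turnover cost also falls with LLS, the negative SLA–LLS ridge.
2. **Support allometry**: the sheath : lamina mass ratio scales as
   `(L0/L0_ref)^0.9` — taller plants carry more non-photosynthetic support
   per unit leaf area.  Sets the height optimum and, with canopy closure,
   the negative TD–H ridge (dense swards meet the optimal LAI with smaller
   leaves).
3. **Per-axis overhead**: a fixed respiration per axis
   (2.5·10⁻⁴ gC axis⁻¹ d⁻¹ at 20 °C for the default grass) for apex and
   pseudostem upkeep.
   Penalises dense tillering once the canopy is closed; interception loss
   penalises sparse swards; together they set the TD optimum and contribute
   the positive TD–SLA ridge (denser swards are C-tighter per axis, which
   favours cheaper leaf area).
4. **Canopy aging**: leaf function declines with absolute thermal age,
   `exp(−age/tau_leaf)`, applied to the usable intercepted light (senescent
   leaves shade young ones) — a cost the coordination loop cannot buy back
   with protein.  Balances the turnover saving of long leaf lifespans and
   sets the LLS optimum.

Species parameter sets centre the reference constants of these laws on the
species' own observed traits (`SLA_ref = SLA_obs`, `L0_ref = L0_obs`,
`tau_leaf = 2.5 · LLS_obs`, `TD_ref = TD0_obs`; the per-axis overhead scales
as `5000/TD_ref` because dense-tillering species have proportionally
smaller, cheaper axes; the self-thinning LAI is 0.75 of the species' own
geometric canopy packing capacity; lamina width is a species constant set
by the observed allometry).  This mirrors field parameterisation, in which
the full parameter set co-varies with a species' trait syndrome: a
conservative species also ages its canopy slowly, a dense-tillering species
is adapted to its own stand density.  The factorial sweep then perturbs
only the four trait-mapped parameters around that species-specific
reference.

### Units, scale and the "average plant"

State is per axis; ledger fluxes per m² ground.  Performance is the mean
annual structural biomass production (shoot + root, including mass later
removed by cutting) per m², divided by a nominal planting density of 2500
plants m⁻², which places it in the 0.2–2 g plant⁻¹ yr⁻¹ range typical of
productive mesic grassland given swards of a few thousand tillers m⁻².
Harvested tissue is counted when grown, not again at cutting.

## The virtual experiment

For each species and N supply level, each trait is given ten equidistant
values spanning ±30% of the observed value plus the observed value itself
(11 values; the observed value is deduplicated when it coincides with a
step).  The full published-scale design — 12 species × 2 N levels × 11⁴
combinations — enumerates to 351 384 runs; the desk-scale default sweeps
2 synthetic archetypes × 2 N levels × 5⁴ combinations with 2 scored years
per run, identical code paths throughout.

Each run spins up to quasi-equilibrium (annual cycles until the annual
aggregates — production, end-of-year tiller density, season-mean substrate
C:N and interception — change by <10⁻³ relative, cap 20 cycles) and then
scores the configured years.  Some parameter sets settle onto an attractor
with a persistent interannual wobble of a few tenths of a percent (leaf
cohort phases never repeat exactly); spin-up also accepts quasi-equilibrium
when the cycle-to-cycle change stops decreasing while below ten times the
tolerance.  Failed runs are recorded per row, never aborting a campaign, and
campaigns are deterministic and independent of execution order.

Calibration helpers optimise (fine-root maximum length, fine-root lifespan)
by maximising equilibrium axis biomass `W_G`, and (tiller apparition,
senescence rates) by fitting equilibrium tiller density, both by coarse-grid
restart plus coordinate golden-section search on the 2-D box; a flat
response returns the box centre.

## Landscape analysis

* **Adaptive peak** (`find_trait_max`): exact argmax over successful rows;
  ties break to the lowest grid-index tuple.  The row's season-mean
  substrate C:N is reported as the optimal C:N.
* **Adaptive ridges** (`fit_ridge`): with two traits fixed at observed
  values, the performance-maximising value of trait *j* is found for each
  grid value of trait *i* (grid nodes, no interpolation; ties to lower *j*),
  and a least-squares line through these local optima gives the slope
  `alpha_ij`.
* **Coordination index** (`alpha_sum`): each slope is nondimensionalised by
  the observed trait ratio, `alpha_rel = alpha · obs_i / obs_j` — the only
  unit-free convention computable from the observed traits alone — and the
  index is the sum of absolute relative slopes over the six pairs.
* **RMA regression**: slope `sign(r) · sd(y)/sd(x)`, intercept through the
  means, for predicted-vs-observed comparisons where both sides carry error.
* **Plasticity prediction** (`predict_plasticity`): the value of one trait
  maximising performance on the high-N landscape when the other three are
  forced (snapped to nearest grid nodes) to their low-N values — the
  conditional argmax, equivalently the ridge logic applied to an
  environmental change.
* **PCA comparison**: correlation-matrix PCA of predicted and observed trait
  matrices (traits have incommensurable units), axis sign fixed by making
  the largest-magnitude loading positive, per-axis OLS of predicted on
  observed species scores with relative RMSE = 100·RMSE/range(observed
  scores).
* **Variance decomposition**: for a pair of standardised diagnostics, each
  variable's incremental R² averaged over both entry orders, normalised to
  sum to 100; pairs with |corr| > 0.999 are reported as undefined.
* **Unimodality** (`is_unimodal`): a profile counts as unimodal when it has
  a single local maximum of topographic prominence above 1% of the peak
  value; smaller wiggles are the discrete-cohort surface texture of the
  daily-step model, not separate adaptive peaks.
* **C:N homeostasis** (`cn_homeostasis`): coefficient of variation of the
  season-mean substrate C:N along the fitted ridge versus along the
  index-space anti-diagonal through the peak (breaking the coordination).

## Synthetic data

`gen_species` draws archetype panels from a Gaussian copula imposing the two
strategy spectra as rank correlations (SLA–LLS ρ = −0.9, H–TD ρ = −0.9) over
trait ranges spanning the packaged 12-species panel — panels lie tightly
along the spectra, as calibrated field panels do.  Physiological rates jitter
by roughly ±10% around genus-typical values, and the target substrate C:N is
derived from the drawn traits through the interspecific structure of the
packaged panel (`C:N ≈ 0.0090·LLS + 0.096·H − 4.11` plus noise, r² = 0.80),
so each archetype's parameter set is internally consistent with its trait
syndrome.  `gen_climate` produces sinusoidal
seasonal PAR and temperature (peak mid-summer, day 172; means 6 MJ m⁻² d⁻¹
and 10 °C, temperate amplitudes) with optional seeded white noise, truncated
at zero PAR.  `gen_management` splits the annual N total (kgN ha⁻¹ yr⁻¹ ÷ 10
→ gN m⁻²) into equal applications (default 4, days 60/120/180/240) and cuts
to 5 cm on days 120/160/200/240.  All generators are pure functions of
(config, seed).

What the generator does *not* emulate: real weather autocorrelation and
extremes, water limitation, within-season management variation, and the
field covariance between traits and the 20-odd physiological parameters
beyond the five varied here.  Tests passing on these synthetic conditions
demonstrate the internal consistency and qualitative structure of the
method — single peaks, ridge signs, substrate homeostasis, plasticity
transfer — not quantitative agreement with any field system.

## Numerical choices and limitations

* Daily Euler step for all pools except tiller density (exact one-day flow);
  thermal time base 0 °C; physiological rates scale linearly with
  temperature to 1 at 20 °C, capped at 25 °C.
* Floors: tiller density ≥ 10 m⁻², substrate N ≥ 10⁻⁹ gN (keeps C:N
  defined); protein removals clamp at zero to absorb float rounding.
* Starvation is graceful: unpayable maintenance is capped at the available
  C pool and growth scales to the remaining supply; a plant can shrink to
  (numerically exact) zero production without aborting the run.  NaN or
  negative state aborts with the day index.
* Co-limitation at equilibrium is approximate: the discrete leaf-cohort
  cycle keeps the fast pools on a small limit cycle around the coordination
  fixed point, and the stoichiometric damping of Q shifts the equilibrium
  away from exact limb equality whenever substrate C:N sits off its target.
  The light and capacity limbs stay within a factor ~1.5 of each other; the
  exact fixed point is a property of the Q update itself.
* The C:N ratio of the substrate pool is a diagnostic of coordination, not a
  control target; storage exchanges a small fraction (5% d⁻¹) of the excess
  over the target stoichiometry with the reserve pools.
* Single-species swards only; no water balance, grazing, reproduction or
  recruitment; no claim of numeric equivalence with any field-parameterised
  model.
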