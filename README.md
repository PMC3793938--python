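# gramscape

Trait-landscape experiments with an individual-centred grass growth model.

Plant functional traits do not vary freely: specific leaf area (SLA) and
leaf lifespan (LLS) trade off along the leaf economics spectrum, and plant
height (H) trades off against tiller density (TD) along the stature
spectrum.  `gramscape` asks the mechanistic question behind those patterns:
if the four traits are varied *independently* in a process model of grass
growth, which combinations maximise performance, and do the observed
correlations re-emerge as ridges of the performance landscape?

The package is for plant ecologists and ecosystem modellers who want a
transparent, fully testable desk-scale implementation of that virtual
experiment: an average-plant simulator with coupled carbon–nitrogen
substrate dynamics and morphogenesis, a factorial trait-grid driver, and
the landscape statistics (adaptive peaks, ridge slopes α, coordination
index, RMA and PCA comparisons, plasticity prediction).

## The model in brief

One average axis (tiller) of a monospecific sward is stepped daily under
PAR, temperature, cutting and N fertilisation.  Labile substrate pools obey

    dW_C/dt = Photosynthesis + Remobilisation − Respiration − Partitioning − Storage − Exudation
    dW_N/dt = Uptake + Fixation + Remobilisation − Partitioning − Storage − Exudation

Growth partitioning follows two coordination principles: a functional
balance between root and shoot activity (root share *P* tracks the
substrate C:N ratio relative to its target) and coordination of leaf
photosynthesis (protein share *Q* drives light-limited and
capacity-limited assimilation to co-limitation).  Morphogenesis produces
leaf cohorts each phyllochron and sheds them at the leaf lifespan; tiller
demography relaxes toward the potential density with self-thinning above a
critical LAI.  The four traits enter as parameters: SLA via leaf dry-matter
content, H via potential lamina length, LLS via the phyllochron, TD as the
initial/potential tiller density.  C and N are conserved to 1e-6 relative
on every simulated day, by construction and by test.

In the virtual experiment each trait takes ten equidistant values spanning
±30% of the species' observed value, plus the observed value itself; the
full crossed design over 12 species and two N supply levels (120 and
360 kgN ha⁻¹ yr⁻¹) enumerates to 351 384 runs.  The desk-scale default
(2 synthetic archetype species, 5 values per trait) runs the identical code
path in minutes.  See `docs/methods.md` for every closure and parameter.

## Worked example

```python
from gramscape import (SpeciesParams, run_simulation, performance,
                       gen_climate, gen_management, ClimateConfig,
                       ManagementConfig)

params = SpeciesParams()                      # a Lolium-like default grass
climate = gen_climate(ClimateConfig(years=1, par_noise_sd=0, temp_noise_sd=0))
schedule = gen_management(ManagementConfig(n_annual=360.0))  # 4 x 9 gN/m2, 4 cuts

traj = run_simulation(params, climate, schedule, years=8)
print(traj.years[["year", "production_total", "harvest", "td_end", "mean_cn"]]
      .tail(3).round(1).to_string(index=False))
print(f"performance: {performance(traj):.3f} g plant^-1 yr^-1")
```

prints

```
 year  production_total  harvest  td_end  mean_cn
    6            4358.6    551.6  4879.0      5.9
    7            4358.6    551.6  4879.0      5.9
    8            4358.6    551.6  4879.0      5.9
performance: 1.741 g plant^-1 yr^-1
```

Annual production (g DM m⁻² yr⁻¹, shoot + root including harvested mass) is
stable year to year under cyclic weather — the quasi-equilibrium the trait
campaigns score.  `performance` is the same quantity per average plant at
the nominal planting density; `mean_cn` is the season-mean substrate C:N
ratio, the in-planta marker of C–N coordination.  A campaign sweeps this
over a trait grid:

```python
from gramscape import CampaignSpec, run_campaign, find_trait_max, gen_species, ArchetypeSpec
from gramscape.analysis import fit_all_ridges

species = gen_species(ArchetypeSpec(n_species=1, seed=1))
spec = CampaignSpec(species=species, n_levels=(360.0,), steps=5, years=2)
table = run_campaign(spec)        # 625 runs, one row each
opt = find_trait_max(table)
print(opt.traits, round(opt.performance, 3), round(opt.cn_opt, 2))
```

The command line mirrors this: `gramscape pipeline --config demo.yaml`
chains species synthesis, campaign and analysis from one YAML config (see
`demo.yaml`), writing `landscape.csv`, `optima.csv` and `ridges.csv`.

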