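"""Shared fixtures: deterministic drivers, schedules, and the campaign tables
used by the landscape-level tests.

The heavy fixtures (factorial campaigns) are session-scoped and computed
once; every test that needs a landscape shares them.
"""

from __future__ import annotations

import numpy as np
import pytest

from gramscape.experiment import CampaignSpec, run_campaign
from gramscape.params import SpeciesParams, traits_from_params
from gramscape.synth import (ArchetypeSpec, ClimateConfig, ManagementConfig,
                             gen_climate, gen_management, gen_species,
                             species_params_from_row)

N_HIGH = 360.0  # kgN ha-1 yr-1
N_LOW = 120.0

#: deterministic single-year climate used everywhere a cyclic driver is needed
CLIMATE_CFG = ClimateConfig(years=1, par_noise_sd=0.0, temp_noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def climate():
    return gen_climate(CLIMATE_CFG)


@pytest.fixture(scope="session")
def schedule_high():
    return gen_management(ManagementConfig(n_annual=N_HIGH))


@pytest.fixture(scope="session")
def schedule_low():
    return gen_management(ManagementConfig(n_annual=N_LOW))


@pytest.fixture()
def params():
    return SpeciesParams()


@pytest.fixture(scope="session")
def archetypes2():
    """The two-species archetype panel of the desk-scale campaign."""
    return gen_species(ArchetypeSpec(n_species=2, seed=1))


@pytest.fixture(scope="session")
def campaign_table(archetypes2):
    """Desk-scale factorial campaign: 2 archetype species x 2 N levels x
    5 values per trait (5^4 combinations), 2 scored years per run."""
    spec = CampaignSpec(species=archetypes2, n_levels=(N_HIGH, N_LOW),
                        steps=5, years=2, climate=CLIMATE_CFG)
    return run_campaign(spec)


@pytest.fixture(scope="session")
def observed_traits(archetypes2):
    """Observed (drawn) trait values per archetype species."""
    out = {}
    for _, row in archetypes2.iterrows():
        base = species_params_from_row(row)
        out[row["species"]] = traits_from_params(base).as_dict()
    return out


def trait_profile(base, observed, trait, climate, schedule, n=7,
                  spin=5, years=3):
    """Performance profile along one trait, other traits at observed."""
    from gramscape.experiment import run_single
    from gramscape.params import TraitVector

    o = observed[trait]
    vals = np.linspace(0.7 * o, 1.3 * o, n)
    perfs = []
    for v in vals:
        tr = TraitVector(**{**observed, trait: v})
        out = run_single(base, tr, climate, schedule, years=years,
                         spin_max_cycles=spin + 3)
        perfs.append(out["performance"])
    return vals, np.array(perfs)
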