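"""Synthetic inputs: species archetypes, daily weather and management schedules.

The generators emulate the three inputs a trait-landscape campaign needs —
a panel of grass species parameter sets spanning realistic trait ranges, a
multi-year daily climate record, and cutting/fertilisation schedules for two
N supply levels — with the statistical structure the analysis assumes:
a negative SLA-LLS rank correlation (leaf economics spectrum) and a negative
H-TD rank correlation (allometric stature spectrum), imposed through a
Gaussian copula on ranks.  All generators are pure functions of their config
and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ManagementEvent
from .params import SpeciesParams, TraitVector, map_traits_to_params

__all__ = [
    "ArchetypeSpec",
    "ClimateConfig",
    "ManagementConfig",
    "gen_species",
    "gen_climate",
    "gen_management",
    "species_params_from_row",
]

#: Default trait ranges spanning the calibrated 12-species panel.
DEFAULT_TRAIT_RANGES = {
    "sla": (126.0, 329.0),   # cm2 g-1
    "h": (30.5, 56.8),       # cm
    "lls": (346.0, 842.0),   # deg C day
    "td0": (2591.0, 10053.0),  # tillers m-2
}

#: Physiological parameters that vary across archetypes, with their ranges.
#: The jitter is modest (~+/-10% around genus-typical values): the panel
#: emulates field-calibrated species whose physiological rates are
#: internally consistent with their trait syndrome, so that trait variation
#: drives the differentiation.
DEFAULT_PHYS_RANGES = {
    "amax_protein": (9.0, 11.0),    # gC gProt-1 d-1
    "umax": (0.054, 0.066),         # gN m-2 root d-1
    "r_maint": (0.0072, 0.0088),    # gC gDM-1 d-1
    "sra": (0.108, 0.132),          # m2 g-1
}

#: Optimal substrate C:N as a function of leaf lifespan and height, the
#: interspecific structure of the calibrated panel (regression over the
#: packaged 12-species table, r2 = 0.80): cn = a*LLS + b*H + c + noise.
CN_TARGET_COEFFS = dict(lls=0.00903, h=0.0962, intercept=-4.113, noise_sd=0.4)


@dataclass(frozen=True)
class ArchetypeSpec:
    """Configuration of the species-archetype generator."""

    n_species: int = 2
    trait_ranges: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_RANGES))
    phys_ranges: dict = field(default_factory=lambda: dict(DEFAULT_PHYS_RANGES))
    rho_sla_lls: float = -0.9
    rho_h_td: float = -0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        for name, (lo, hi) in {**self.trait_ranges, **self.phys_ranges}.items():
            if not (0 < lo <= hi):
                raise ValueError(f"range for {name} must be positive and ordered")


@dataclass(frozen=True)
class ClimateConfig:
    """Configuration of the seasonal daily-weather generator."""

    years: int = 1
    par_mean: float = 6.0       # annual mean PAR (MJ m-2 d-1)
    par_amp: float = 0.8        # relative seasonal amplitude of PAR
    temp_mean: float = 10.0     # annual mean temperature (deg C)
    temp_amp: float = 8.0       # seasonal temperature amplitude (deg C)
    par_noise_sd: float = 1.0   # day-to-day PAR noise sd (MJ m-2 d-1)
    temp_noise_sd: float = 1.5  # day-to-day temperature noise sd (deg C)
    seed: int = 0

    def __post_init__(self):
        if self.years < 1:
            raise ValueError("years must be >= 1")


@dataclass(frozen=True)
class ManagementConfig:
    """Configuration of the cutting + split-fertilisation schedule."""

    n_annual: float = 360.0     # annual N fertilisation (kgN ha-1 yr-1)
    n_applications: int = 4
    fert_days: tuple = (60, 120, 180, 240)
    cut_days: tuple = (120, 160, 200, 240)
    residual_height: float = 5.0  # cm
    seed: int = 0

    def __post_init__(self):
        if self.n_annual < 0:
            raise ValueError("n_annual must be nonnegative")
        if self.n_applications and len(self.fert_days) < self.n_applications:
            raise ValueError("not enough fert_days for n_applications")


def gen_species(spec: ArchetypeSpec) -> pd.DataFrame:
    """Draw a species parameter table with trait-spectrum correlations.

    The four traits are drawn from a Gaussian copula whose correlation matrix
    imposes negative SLA-LLS and H-TD dependence, then mapped through the
    marginal uniform ranges; physiological parameters are drawn independently
    from their ranges.  Columns carry the same names and units as the
    packaged species table plus the physiological entries.
    """
    rng = np.random.default_rng(spec.seed)
    order = ["sla", "h", "lls", "td0"]
    corr = np.eye(4)
    corr[0, 2] = corr[2, 0] = spec.rho_sla_lls
    corr[1, 3] = corr[3, 1] = spec.rho_h_td
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((spec.n_species, 4)) @ chol.T
    from scipy.stats import norm
    u = norm.cdf(z)
    rows = []
    for i in range(spec.n_species):
        row = {"species": f"archetype_{i:02d}", "code": f"A{i:02d}"}
        for j, t in enumerate(order):
            lo, hi = spec.trait_ranges[t]
            row[t] = lo + (hi - lo) * u[i, j]
        for name, (lo, hi) in spec.phys_ranges.items():
            row[name] = rng.uniform(lo, hi)
        cc = CN_TARGET_COEFFS
        row["cn_target"] = float(np.clip(
            cc["intercept"] + cc["lls"] * row["lls"] + cc["h"] * row["h"]
            + rng.normal(0.0, cc["noise_sd"]), 2.0, 8.0))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.rename(columns={"sla": "sla_cm2_g", "h": "h_cm",
                              "lls": "lls_Cday", "td0": "td_m2"})


#: tau_leaf / lls ratio used to co-adapt leaf aging with the observed lifespan.
TAU_LEAF_PER_LLS = 2.5


def species_params_from_row(row, base: SpeciesParams | None = None) -> SpeciesParams:
    """Build a full parameter set from one row of a species table.

    Besides mapping the four traits, the allometric reference parameters are
    centred on the species' own observed values (sla_ref, l0_ref, td_ref,
    tau_leaf), mirroring field parameterisation where the whole parameter set
    co-varies with a species' traits: a conservative, long-lived-leaf species
    also ages its canopy more slowly, a dense-tillering species is adapted to
    its own stand density.  The trait sweep of a virtual experiment then
    varies only the four trait-mapped parameters around this species-specific
    reference.
    """
    base = base or SpeciesParams()
    phys_cols = list(DEFAULT_PHYS_RANGES) + ["cn_target"]
    phys = {k: float(row[k]) for k in phys_cols if k in row and pd.notna(row[k])}
    traits = TraitVector(sla=float(row["sla_cm2_g"]), h=float(row["h_cm"]),
                         lls=float(row["lls_Cday"]), td0=float(row["td_m2"]))
    base = base.replace(
        sla_ref=traits.sla,
        l0_ref=traits.h / base.height_shape_factor,
        td_ref=traits.td0,
        tau_leaf=TAU_LEAF_PER_LLS * traits.lls,
        **phys,
    )
    return map_traits_to_params(traits, base)


def gen_climate(cfg: ClimateConfig) -> pd.DataFrame:
    """Generate ``365 * years`` days of PAR and temperature.

    Both follow a sinusoid peaking at mid-summer (day 172) plus seeded white
    noise; PAR is truncated at zero.  With zero noise the annual cycle is
    identical every year.  Columns: day, par_MJ_m2, temp_C.
    """
    rng = np.random.default_rng(cfg.seed)
    n = 365 * cfg.years
    day = np.arange(1, n + 1)
    doy = (day - 1) % 365 + 1
    season = np.sin(2.0 * np.pi * (doy - 81) / 365.0)  # peaks at day ~172
    par = cfg.par_mean * (1.0 + cfg.par_amp * season)
    temp = cfg.temp_mean + cfg.temp_amp * season
    if cfg.par_noise_sd > 0:
        par = par + rng.normal(0.0, cfg.par_noise_sd, n)
    if cfg.temp_noise_sd > 0:
        temp = temp + rng.normal(0.0, cfg.temp_noise_sd, n)
    par = np.maximum(par, 0.0)
    return pd.DataFrame({"day": day, "par_MJ_m2": par, "temp_C": temp})


def gen_management(cfg: ManagementConfig) -> list[ManagementEvent]:
    """Build the annual management schedule.

    The annual N total (kgN ha-1 yr-1, i.e. /10 gN m-2 yr-1) is split into
    equal applications on the configured days; cuts happen on the configured
    days at the configured residual height.  Duplicate same-day events of the
    same kind are rejected.
    """
    events: list[ManagementEvent] = []
    if cfg.n_annual > 0 and cfg.n_applications > 0:
        per_event = cfg.n_annual / 10.0 / cfg.n_applications  # gN m-2
        days = cfg.fert_days[: cfg.n_applications]
        if len(set(days)) != len(days):
            raise ValueError("duplicate fertilisation days")
        for d in days:
            events.append(ManagementEvent(day=int(d), kind="fertilize",
                                          magnitude=per_event))
    if len(set(cfg.cut_days)) != len(cfg.cut_days):
        raise ValueError("duplicate cut days")
    for d in cfg.cut_days:
        events.append(ManagementEvent(day=int(d), kind="cut",
                                      magnitude=cfg.residual_height))
    events.sort(key=lambda e: e.day)
    return events
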