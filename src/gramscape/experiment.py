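"""Factorial trait-grid campaigns: build grids, spin up, sweep, calibrate.

A campaign crosses, for every species and N supply level, a grid per trait of
ten equidistant values spanning +/-30% of the observed value plus the
observed value itself, runs the simulator to quasi-equilibrium (spin-up) and
then for a scoring period, and collects one row of performance and
diagnostics per trait combination into a landscape table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (ManagementEvent, PlantState, SimulationError, performance,
                    run_simulation)
from .params import SpeciesParams, TraitVector, map_traits_to_params, traits_from_params
from .synth import (ClimateConfig, ManagementConfig, gen_climate,
                    gen_management, species_params_from_row)

__all__ = [
    "CampaignSpec",
    "build_trait_grid",
    "enumerate_design",
    "spin_up",
    "run_campaign",
    "run_single",
    "calibrate_root_params",
    "calibrate_demography",
    "LANDSCAPE_COLUMNS",
]

TRAIT_NAMES = ("sla", "h", "lls", "td0")

LANDSCAPE_COLUMNS = [
    "species", "n_level",
    "sla", "h", "lls", "td0",
    "i_sla", "i_h", "i_lls", "i_td0",
    "performance", "mean_cn", "mean_f_int", "mean_net_photo", "mean_su",
    "nue", "rue", "mean_p", "mean_q", "sra", "status",
]


def build_trait_grid(observed: float, fraction: float = 0.30,
                     steps: int = 10) -> np.ndarray:
    """Grid of ``steps`` equidistant values spanning ``+/-fraction`` around
    the observed value, with the observed value inserted (deduplicated when
    it coincides with a step), sorted ascending.
    """
    if not observed > 0:
        raise ValueError("observed trait value must be positive")
    if steps < 2:
        raise ValueError("steps must be >= 2")
    vals = np.linspace((1.0 - fraction) * observed, (1.0 + fraction) * observed, steps)
    if not np.any(np.isclose(vals, observed, rtol=1e-12, atol=0.0)):
        vals = np.append(vals, observed)
    return np.sort(vals)


def enumerate_design(grids: dict[str, np.ndarray] | list, n_species: int = 1,
                     n_levels: int = 1) -> int:
    """Exact number of simulation runs of a fully crossed design."""
    sizes = grids.values() if isinstance(grids, dict) else grids
    count = n_species * n_levels
    for g in sizes:
        count *= len(g) if np.ndim(g) else int(g)
    return count


@dataclass(frozen=True)
class CampaignSpec:
    """Everything needed to reproduce a trait-landscape campaign."""

    species: pd.DataFrame            # one row per species (trait columns as in synth)
    n_levels: tuple = (360.0, 120.0)  # annual N fertilisation (kgN ha-1 yr-1)
    fraction: float = 0.30
    steps: int = 10
    years: int = 10                   # scored years per run
    spin_tol: float = 1e-3
    spin_max_cycles: int = 20
    climate: ClimateConfig = field(default_factory=lambda: ClimateConfig(
        years=1, par_noise_sd=0.0, temp_noise_sd=0.0, seed=0))
    management: ManagementConfig = field(default_factory=ManagementConfig)
    seed: int = 0

    def __post_init__(self):
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if any(n <= 0 for n in self.n_levels):
            raise ValueError("N levels must be positive")


def spin_up(params: SpeciesParams, drivers, schedule: list[ManagementEvent],
            tol: float = 1e-3, max_cycles: int = 20,
            soil_n: float = 2.0) -> tuple[PlantState, float, bool, int]:
    """Repeat annual cycles until the end-of-year state is stationary.

    Convergence is judged on annual aggregates (total production, end-of-year
    tiller density, season-mean substrate C:N and light interception): the
    daily-step model retains a small sub-annual phase jitter in its fast
    pools (leaf cohort ages never repeat exactly year to year), while the
    annual integrals become stationary.  Relative change of every aggregate
    over one cycle must fall below ``tol``.  Returns (state, soil_n,
    converged, cycles); a run hitting ``max_cycles`` without convergence is
    reported, not fatal.

    Some parameter sets settle onto an attractor with a small persistent
    interannual wobble (a few tenths of a percent) rather than an exact
    annual cycle; spin-up therefore also accepts quasi-equilibrium when the
    cycle-to-cycle change has stopped decreasing while sitting below ten
    times the tolerance.
    """
    state = None
    prev = None
    converged = False
    cycles = 0
    changes: list[float] = []
    for cycles in range(1, max_cycles + 1):
        traj = run_simulation(params, drivers, schedule, years=1,
                              state=state, soil_n=soil_n)
        state = traj.final_state
        soil_n = traj.totals["soil_n1"]
        y = traj.years.iloc[0]
        vec = np.array([y["production_total"], y["td_end"],
                        y["mean_cn"], y["mean_f_int"]])
        if prev is not None:
            ref = np.maximum(np.abs(prev), 1e-9)
            change = float(np.max(np.abs(vec - prev) / ref))
            changes.append(change)
            if change < tol:
                converged = True
                break
            if (cycles >= 5 and change < 10.0 * tol
                    and change >= min(changes[:-1])):
                converged = True  # stationary wobble around the attractor
                break
        prev = vec
    return state, soil_n, converged, cycles


def run_single(base: SpeciesParams, traits: TraitVector, drivers,
               schedule: list[ManagementEvent], years: int,
               spin_tol: float = 1e-3, spin_max_cycles: int = 20) -> dict:
    """Map traits, spin up, run the scored years and summarise one row."""
    params = map_traits_to_params(traits, base)
    state, soil_n, _, _ = spin_up(params, drivers, schedule,
                                  tol=spin_tol, max_cycles=spin_max_cycles)
    traj = run_simulation(params, drivers, schedule, years=years,
                          state=state, soil_n=soil_n)
    y = traj.years
    return dict(
        performance=performance(traj),
        mean_cn=float(y["mean_cn"].mean()),
        mean_f_int=float(y["mean_f_int"].mean()),
        mean_net_photo=float(y["mean_net_photo"].mean()),
        mean_su=float(y["mean_su"].mean()),
        nue=float(y["nue"].mean()),
        rue=float(y["rue"].mean()),
        mean_p=float(y["mean_p"].mean()),
        mean_q=float(y["mean_q"].mean()),
        sra=params.sra_eff,
    )


def run_campaign(spec: CampaignSpec, progress=None) -> pd.DataFrame:
    """Run the fully crossed campaign and return the landscape table.

    One row per species x N level x trait combination.  Failed runs are
    recorded with status "failed" (performance NaN) and never abort the
    campaign.  The result is deterministic given the spec and independent of
    execution order.
    """
    drivers = gen_climate(spec.climate)
    rows = []
    for _, srow in spec.species.iterrows():
        base = species_params_from_row(srow)
        observed = traits_from_params(base)
        grids = {t: build_trait_grid(getattr(observed, t), spec.fraction, spec.steps)
                 for t in TRAIT_NAMES}
        for n_level in spec.n_levels:
            mgmt = ManagementConfig(
                n_annual=n_level,
                n_applications=spec.management.n_applications,
                fert_days=spec.management.fert_days,
                cut_days=spec.management.cut_days,
                residual_height=spec.management.residual_height,
            )
            schedule = gen_management(mgmt)
            for idx in itertools.product(*(range(len(grids[t])) for t in TRAIT_NAMES)):
                tvals = {t: float(grids[t][i]) for t, i in zip(TRAIT_NAMES, idx)}
                row = dict(species=srow["species"], n_level=n_level, **tvals)
                for t, i in zip(TRAIT_NAMES, idx):
                    row["i_" + t] = i
                try:
                    traits = TraitVector(**tvals)
                    out = run_single(base, traits, drivers, schedule, spec.years,
                                     spec.spin_tol, spec.spin_max_cycles)
                    row.update(out)
                    row["status"] = "ok"
                except (SimulationError, ValueError, FloatingPointError):
                    row.update({k: math.nan for k in
                                ("performance", "mean_cn", "mean_f_int",
                                 "mean_net_photo", "mean_su", "nue", "rue",
                                 "mean_p", "mean_q", "sra")})
                    row["status"] = "failed"
                rows.append(row)
                if progress is not None:
                    progress(row)
    return pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS)


# ---------------------------------------------------------------------------
# calibration optimisers
# ---------------------------------------------------------------------------

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section_max(f, lo, hi, tol, max_iter=40):
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


def _maximize_2d(f, bounds, coarse: int = 5, sweeps: int = 3,
                 rel_tol: float = 1e-3):
    """Maximise f over a 2-D box: coarse-grid restart then coordinate-wise
    golden-section search.  A flat response returns the box centre.
    """
    (x_lo, x_hi), (y_lo, y_hi) = bounds
    xs = np.linspace(x_lo, x_hi, coarse)
    ys = np.linspace(y_lo, y_hi, coarse)
    vals = np.array([[f(x, y) for y in ys] for x in xs])
    if np.allclose(vals, vals.flat[0], rtol=1e-12, atol=0.0):
        cx, cy = (x_lo + x_hi) / 2.0, (y_lo + y_hi) / 2.0
        return cx, cy, f(cx, cy)
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    x, y = float(xs[i]), float(ys[j])
    best = float(vals[i, j])
    for _ in range(sweeps):
        x, best = _golden_section_max(lambda u: f(u, y), x_lo, x_hi,
                                      rel_tol * (x_hi - x_lo))
        y, best = _golden_section_max(lambda v: f(x, v), y_lo, y_hi,
                                      rel_tol * (y_hi - y_lo))
    return x, y, best


def _equilibrium_state(params, drivers, schedule, tol=1e-3, max_cycles=12):
    state, _, _, _ = spin_up(params, drivers, schedule, tol=tol,
                             max_cycles=max_cycles)
    return state


def calibrate_root_params(params: SpeciesParams, drivers, schedule,
                          bounds=((10.0, 80.0), (200.0, 1500.0)),
                          objective=None) -> dict:
    """Optimise fine-root maximum length and lifespan by maximising the
    equilibrium per-axis structural biomass W_G.

    ``objective(root_max_length, root_lifespan) -> float`` may be supplied
    (e.g. for testing against an exhaustive grid); the default runs the model
    to equilibrium.  Returns the argmax and the attained W_G.
    """
    if objective is None:
        def objective(rl, rt):
            p = params.replace(root_max_length=rl, root_lifespan=rt)
            state = _equilibrium_state(p, drivers, schedule)
            return state.w_axis(p)
    rl, rt, w_g = _maximize_2d(objective, bounds)
    return dict(root_max_length=rl, root_lifespan=rt, w_axis=w_g)


def calibrate_demography(params: SpeciesParams, observed_td: float, drivers,
                         schedule, bounds=((0.005, 0.2), (0.005, 0.2)),
                         objective=None) -> dict:
    """Optimise tiller apparition and senescence rates by fitting the
    equilibrium tiller density to the observed one (least squares).
    """
    if not observed_td > 0:
        raise ValueError("observed_td must be positive")
    if objective is None:
        def objective(app, sen):
            p = params.replace(tiller_app_rate=app, tiller_sen_rate=sen)
            state = _equilibrium_state(p, drivers, schedule)
            return -(state.td - observed_td) ** 2
    app, sen, neg_sq = _maximize_2d(objective, bounds)
    return dict(tiller_app_rate=app, tiller_sen_rate=sen,
                residual=math.sqrt(max(-neg_sq, 0.0)))
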