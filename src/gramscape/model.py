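"""Daily-step individual-centred grass growth model with coupled C-N substrate pools.

The model follows one *average plant axis* (tiller) of a monospecific grass
sward, plus the tiller density of the population, through daily time steps
driven by incident PAR, mean air temperature and discrete management events
(cutting, N fertilisation).  Growth is fuelled by two labile substrate pools,
carbon ``W_C`` and nitrogen ``W_N``, whose mass balances read::

    dW_C/dt = Photosynthesis + Remobilisation - Respiration - Partitioning - Storage - Exudation
    dW_N/dt = Uptake + Fixation + Remobilisation - Partitioning - Storage - Exudation

(fixation and exudation are zero for these grasses).  Partitioning of growth
between roots, shoot structure and leaf photosynthetic protein is governed by
two slowly relaxing coefficients: ``P`` (root share, functional balance
between root and shoot activity) and ``Q`` (protein share of shoot growth,
coordination of leaf photosynthesis so that light-limited and
capacity-limited assimilation co-limit).

Morphogenesis produces leaf cohorts every phyllochron, extends them toward a
potential lamina length, and senesces them at the leaf lifespan; tiller
demography couples apparition (toward the potential tiller density) with
self-thinning above a critical leaf area index.

All state is per axis; ledger fluxes are reported per m2 ground so that
closed-system C and N balances can be verified exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .params import SpeciesParams

__all__ = [
    "SubstratePools",
    "AllocationCoefficients",
    "LeafCohort",
    "PlantState",
    "DailyDriver",
    "ManagementEvent",
    "Trajectory",
    "SimulationError",
    "light_interception",
    "photosynthesis",
    "n_uptake",
    "substrate_balance",
    "functional_balance_p",
    "coordination_q",
    "growth_and_respiration",
    "morphogenesis_step",
    "tiller_rate",
    "tiller_dynamics",
    "apply_management",
    "step_day",
    "run_simulation",
    "initial_state",
    "performance",
    "temperature_factor",
]

WN_FLOOR = 1e-9  # gN; keeps the substrate C:N ratio defined


class SimulationError(RuntimeError):
    """A numerical failure (NaN or negative pool) aborted the run."""

    def __init__(self, message: str, day: int | None = None):
        super().__init__(message if day is None else f"day {day}: {message}")
        self.day = day


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class SubstratePools:
    """Labile C and N substrate masses of one average axis (gC, gN)."""

    wc: float = 0.0
    wn: float = 0.0

    @property
    def cn_ratio(self) -> float:
        return self.wc / max(self.wn, WN_FLOOR)

    def copy(self) -> "SubstratePools":
        return SubstratePools(self.wc, self.wn)


@dataclass
class AllocationCoefficients:
    """Partitioning coefficients P (root share) and Q (protein share)."""

    p: float = 0.35
    q: float = 0.3


@dataclass
class LeafCohort:
    """One leaf generation on the average axis.

    Mass is the stored quantity; area and length follow from the governing
    parameters (area = mass * SLA, length from the fixed lamina shape), which
    keeps the mass = area / SLA invariant exact.
    """

    age: float  # thermal age (deg C day)
    mass: float  # lamina structural dry mass (g)

    def area(self, params: SpeciesParams) -> float:
        """Lamina area (cm2)."""
        return self.mass * params.sla

    def length(self, params: SpeciesParams) -> float:
        """Lamina length (cm), from area = form_factor * length * width."""
        return self.area(params) / (params.form_factor * params.leaf_width)


@dataclass
class PlantState:
    """Full state of the average plant axis plus population tiller density."""

    substrate: SubstratePools
    alloc: AllocationCoefficients
    leaves: list[LeafCohort]
    w_root: float = 0.0       # root structural mass (g per axis)
    w_protein: float = 0.0    # photosynthetic protein mass (g per axis)
    reserves_c: float = 0.0   # C reserve pool (gC per axis)
    reserves_n: float = 0.0   # N reserve pool (gN per axis)
    td: float = 1000.0        # tiller density (axes m-2)
    height: float = 0.0       # realized plant height (cm)
    tt: float = 0.0           # cumulative thermal time (deg C day)
    tt_since_leaf: float = 0.0  # thermal time since the last leaf appeared

    def lamina_mass(self) -> float:
        return sum(c.mass for c in self.leaves)

    def w_shoot(self, params: SpeciesParams) -> float:
        """Shoot structural mass: laminae plus their sheath share (g per axis)."""
        return (1.0 + params.sheath_eff) * self.lamina_mass()

    def lamina_area(self, params: SpeciesParams) -> float:
        """Total lamina area per axis (cm2)."""
        return self.lamina_mass() * params.sla

    def lai(self, params: SpeciesParams) -> float:
        """Leaf area index of the sward (m2 m-2)."""
        return self.td * self.lamina_area(params) * 1e-4

    def leaf_efficiency(self, params: SpeciesParams) -> float:
        """Area-weighted photosynthetic efficiency of the canopy in [0, 1].

        Leaf function declines with absolute thermal age (exp(-age/tau_leaf)),
        so long-lived canopies carry old, inefficient leaves.
        """
        tot = self.lamina_mass()
        if tot <= 0.0:
            return 1.0
        s = sum(c.mass * math.exp(-c.age / params.tau_leaf) for c in self.leaves)
        return s / tot

    def w_axis(self, params: SpeciesParams) -> float:
        """Per-axis structural biomass W_G (g)."""
        return self.w_shoot(params) + self.w_root + self.w_protein

    def plant_c(self, params: SpeciesParams) -> float:
        """Total plant C per axis (gC), structural + protein + substrates + reserves."""
        return (params.c_struct * (self.w_shoot(params) + self.w_root)
                + params.c_protein * self.w_protein
                + self.substrate.wc + self.reserves_c)

    def plant_n(self, params: SpeciesParams) -> float:
        """Total plant N per axis (gN)."""
        return (params.n_struct * (self.w_shoot(params) + self.w_root)
                + params.n_protein * self.w_protein
                + self.substrate.wn + self.reserves_n)

    def copy(self) -> "PlantState":
        return PlantState(
            substrate=self.substrate.copy(),
            alloc=AllocationCoefficients(self.alloc.p, self.alloc.q),
            leaves=[LeafCohort(c.age, c.mass) for c in self.leaves],
            w_root=self.w_root, w_protein=self.w_protein,
            reserves_c=self.reserves_c, reserves_n=self.reserves_n,
            td=self.td, height=self.height, tt=self.tt,
            tt_since_leaf=self.tt_since_leaf,
        )

    def state_vector(self, params: SpeciesParams) -> list[float]:
        """Aggregate state snapshot (masses, substrate pools, density)."""
        return [self.w_shoot(params), self.w_root, self.w_protein,
                self.substrate.wc, self.substrate.wn, self.td]


@dataclass(frozen=True)
class DailyDriver:
    """One day of climate forcing."""

    day: int          # 1-based day index within the run
    par: float        # incident PAR (MJ m-2 d-1)
    temp: float       # mean air temperature (deg C)

    def __post_init__(self):
        if self.par < 0:
            raise ValueError("par must be nonnegative")


@dataclass(frozen=True)
class ManagementEvent:
    """A discrete management action, scheduled by day of year (1..365)."""

    day: int
    kind: str         # "cut" | "fertilize"
    magnitude: float  # residual height (cm) for cut, gN m-2 added for fertilize

    def __post_init__(self):
        if self.kind not in ("cut", "fertilize"):
            raise ValueError(f"unknown management kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")


# ---------------------------------------------------------------------------
# process functions
# ---------------------------------------------------------------------------


def temperature_factor(temp: float) -> float:
    """Thermal limitation of physiological rates, 1 at 20 deg C, 0 below 0."""
    return min(max(temp, 0.0), 25.0) / 20.0


def light_interception(lai: float, k_ext: float) -> float:
    """Fraction of incident light intercepted by the canopy (Beer-Lambert)."""
    if lai < 0:
        raise ValueError("lai must be nonnegative")
    if k_ext <= 0:
        raise ValueError("k_ext must be positive")
    return 1.0 - math.exp(-k_ext * lai)


def photosynthesis(par_int: float, w_protein: float, params: SpeciesParams,
                   f_temp: float = 1.0) -> float:
    """Gross C gain of one axis (gC d-1): smooth minimum of the light-limited
    rate ``eps_light * par_int`` and the capacity-limited rate
    ``amax_protein * w_protein * f_temp``.

    The smooth minimum is the smaller root of
    ``theta A^2 - (x + y) A + x y = 0`` and never exceeds either limb.
    """
    if par_int < 0 or w_protein < 0:
        raise ValueError("inputs must be nonnegative")
    x = params.eps_light * par_int
    y = params.amax_protein * w_protein * f_temp
    if x <= 0.0 or y <= 0.0:
        return 0.0
    th = params.smooth_theta
    s = x + y
    return (s - math.sqrt(s * s - 4.0 * th * x * y)) / (2.0 * th)


def n_uptake(w_root: float, sra: float, soil_n: float, umax: float, km: float,
             f_temp: float = 1.0, td: float = 1.0,
             cap_frac: float = 1.0) -> float:
    """Michaelis-Menten N uptake of one axis (gN d-1).

    ``umax * sra * w_root * soil_n / (km + soil_n)``, capped so the whole
    population cannot extract more than ``cap_frac`` of the soil pool per day.
    """
    if min(w_root, sra, soil_n, umax, km) < 0:
        raise ValueError("inputs must be nonnegative")
    u = umax * sra * w_root * soil_n / (km + soil_n) * f_temp
    if td > 0:
        u = min(u, cap_frac * soil_n / td)
    return u


def substrate_balance(pools: SubstratePools, fluxes: dict[str, float]) -> SubstratePools:
    """Apply one day of signed substrate fluxes to the C and N pools.

    ``fluxes`` may contain (missing entries default to 0): photosynthesis,
    remobilisation_c, respiration, partitioning_c, storage_c, exudation_c,
    uptake, fixation, remobilisation_n, partitioning_n, storage_n,
    exudation_n.  Source terms add, sink terms subtract, exactly as in the
    balance equations.  If a sink overdraws a pool, all sinks of that element
    are scaled by the common factor that keeps the pool nonnegative; a
    residual deficit beyond floating-point slack is a contract violation.
    """
    g = fluxes.get
    src_c = g("photosynthesis", 0.0) + g("remobilisation_c", 0.0)
    snk_c = g("respiration", 0.0) + g("partitioning_c", 0.0) + g("storage_c", 0.0) \
        + g("exudation_c", 0.0)
    src_n = g("uptake", 0.0) + g("fixation", 0.0) + g("remobilisation_n", 0.0)
    snk_n = g("partitioning_n", 0.0) + g("storage_n", 0.0) + g("exudation_n", 0.0)

    wc = pools.wc + src_c - snk_c
    if wc < 0.0:
        avail = pools.wc + src_c
        scale = avail / snk_c if snk_c > 0 else 0.0
        if scale < -1e-9:
            raise SimulationError("C sink demand exceeds supply after down-scaling")
        wc = avail - scale * snk_c  # == 0 up to rounding
        wc = max(wc, 0.0)
    wn = pools.wn + src_n - snk_n
    if wn < 0.0:
        avail = pools.wn + src_n
        scale = avail / snk_n if snk_n > 0 else 0.0
        if scale < -1e-9:
            raise SimulationError("N sink demand exceeds supply after down-scaling")
        wn = max(avail - scale * snk_n, 0.0)
    return SubstratePools(wc, wn)


def functional_balance_p(pools: SubstratePools, params: SpeciesParams,
                         alloc: AllocationCoefficients) -> float:
    """Relax the root allocation coefficient P toward its functional-balance
    target ``p_ref * (C:N / C:N_target)`` clipped to [p_min, p_max].

    N-scarce plants (high substrate C:N) shift allocation below ground.
    """
    target = params.p_ref * pools.cn_ratio / params.cn_target
    target = min(max(target, params.p_min), params.p_max)
    return alloc.p + (target - alloc.p) / params.tau_p


def coordination_q(light_rate: float, capacity_rate: float,
                   alloc: AllocationCoefficients, params: SpeciesParams,
                   pools: SubstratePools | None = None) -> float:
    """Relax the protein allocation coefficient Q toward photosynthetic
    co-limitation: Q rises while the light-limited rate exceeds the
    capacity-limited rate and falls otherwise; at the fixed point the two
    limbs are equal.

    When the substrate pools are supplied, a stoichiometric term damps Q
    while the substrate C:N ratio sits above its target (and boosts it
    below): a plant accumulating excess C downsizes its photosynthetic
    machinery until the acquisition of C and N co-limit, rather than
    fixing C it cannot use.
    """
    if light_rate < 0 or capacity_rate < 0:
        raise ValueError("rates must be nonnegative")
    tot = light_rate + capacity_rate
    dq = 0.0
    if tot > 0.0:
        dq += (light_rate - capacity_rate) / tot
    if pools is not None:
        dq -= params.q_stoich * (pools.cn_ratio / params.cn_target - 1.0)
    if dq == 0.0:
        return alloc.q
    return min(max(alloc.q + dq / params.tau_q, 0.0), 1.0)


def growth_and_respiration(pools: SubstratePools, state: PlantState,
                           params: SpeciesParams, alloc: AllocationCoefficients,
                           f_temp: float = 1.0, d_tt: float = 0.0) -> dict[str, float]:
    """Compute one day of structural growth, respiration and the implied
    substrate partitioning fluxes.

    Total growth follows a supply/demand law with bilinear substrate control::

        G = g_max * f_temp * wc/(wc + kc W) * wn/(wn + kn W) * W

    split root:shoot by P and shoot structure:protein by Q, with each sink
    additionally capped by its morphogenetic capacity (lamina extension rate
    and potential size, maximum root mass, maximum protein load).  Maintenance
    respiration has first call on C; growth is down-scaled by a common factor
    whenever the substrate pools cannot cover its stoichiometric C and N
    costs, so pools never go negative.
    """
    W = state.w_axis(params)
    wc, wn = pools.wc, pools.wn
    if W <= 0.0:
        return dict(g_shoot=0.0, g_root=0.0, g_protein=0.0,
                    maintenance=0.0, growth_resp=0.0,
                    partitioning_c=0.0, partitioning_n=0.0)
    g_pot = (params.g_max * f_temp * W
             * wc / (wc + params.kc * W)
             * wn / (wn + params.kn * W))

    # morphogenetic sink capacities
    expand_tt = params.expand_phyllochrons * params.phyllochron
    m_max = params.lamina_mass_max
    lam_sink = 0.0
    for c in state.leaves:
        if c.age < expand_tt and c.mass < m_max:
            lam_sink += min(m_max - c.mass, m_max * d_tt / expand_tt)
    shoot_sink = (1.0 + params.sheath_eff) * lam_sink
    root_sink = max(0.0, params.w_root_max - state.w_root) * min(1.0, d_tt / 200.0)
    prot_sink = max(0.0, params.protein_frac_max * state.lamina_mass() - state.w_protein)

    p, q = alloc.p, alloc.q
    g_root = min(p * g_pot, root_sink)
    g_shoot = min((1.0 - p) * (1.0 - q) * g_pot, shoot_sink)
    g_prot = min((1.0 - p) * q * g_pot, prot_sink)

    # maintenance has priority on the C pool; includes a fixed per-axis
    # overhead (apex and pseudostem upkeep)
    maint = min(params.r_maint_eff * f_temp * W + params.r_axis_eff * f_temp, wc)
    avail_c = wc - maint

    c_cost = (params.c_struct * (g_shoot + g_root) + params.c_protein * g_prot) / params.y_growth
    n_cost = params.n_struct * (g_shoot + g_root) + params.n_protein * g_prot
    scale = 1.0
    if c_cost > 0.0:
        scale = min(scale, avail_c / c_cost)
    if n_cost > 0.0:
        scale = min(scale, max(wn - WN_FLOOR, 0.0) / n_cost)
    scale = max(0.0, min(1.0, scale))
    g_shoot *= scale
    g_root *= scale
    g_prot *= scale

    tissue_c = params.c_struct * (g_shoot + g_root) + params.c_protein * g_prot
    growth_resp = tissue_c * (1.0 - params.y_growth) / params.y_growth
    part_n = params.n_struct * (g_shoot + g_root) + params.n_protein * g_prot
    return dict(g_shoot=g_shoot, g_root=g_root, g_protein=g_prot,
                maintenance=maint, growth_resp=growth_resp,
                partitioning_c=tissue_c, partitioning_n=part_n)


def morphogenesis_step(state: PlantState, d_tt: float, params: SpeciesParams,
                       g_shoot: float = 0.0) -> dict[str, float]:
    """Advance leaf demography by ``d_tt`` degree-days.

    A new cohort appears at every phyllochron crossing; the shoot structural
    growth of the day (lamina share of ``g_shoot``) is distributed over
    expanding cohorts in proportion to their remaining sink; cohorts older
    than the leaf lifespan are shed, their mass (lamina + sheath share) goes
    to litter and ``remob_frac`` of their N returns to the substrate N pool.
    Root turnover is handled here as well.  Returns the per-axis litter and
    remobilisation amounts.
    """
    if d_tt < 0:
        raise ValueError("d_tt must be nonnegative")
    state.tt += d_tt
    state.tt_since_leaf += d_tt
    for c in state.leaves:
        c.age += d_tt
    while state.tt_since_leaf >= params.phyllochron:
        state.tt_since_leaf -= params.phyllochron
        state.leaves.append(LeafCohort(age=state.tt_since_leaf, mass=0.0))

    # distribute lamina growth over expanding cohorts
    lam_growth = g_shoot / (1.0 + params.sheath_eff)
    if lam_growth > 0.0:
        expand_tt = params.expand_phyllochrons * params.phyllochron
        m_max = params.lamina_mass_max
        sinks = []
        tot = 0.0
        for c in state.leaves:
            s = 0.0
            if c.age < expand_tt and c.mass < m_max:
                s = min(m_max - c.mass, m_max * max(d_tt, 1e-12) / expand_tt)
            sinks.append(s)
            tot += s
        if tot > 0.0:
            for c, s in zip(state.leaves, sinks):
                c.mass += lam_growth * s / tot
        else:
            # sink vanished between the growth step and morphogenesis (aging,
            # new cohort); deposit in the youngest leaf to conserve mass
            if not state.leaves:
                state.leaves.append(LeafCohort(age=0.0, mass=0.0))
            state.leaves[-1].mass += lam_growth

    # leaf senescence: gradual shedding over the last sen_window_frac of the
    # lifespan, full removal at age >= lls
    lls = params.lls
    window = params.sen_window_frac * lls
    lam_total = state.lamina_mass()
    shed_mass = 0.0
    keep = []
    for c in state.leaves:
        if c.age >= lls:
            shed_mass += c.mass
        else:
            if window > 0.0 and c.age > lls - window and c.mass > 0.0 and d_tt > 0.0:
                dm = min(c.mass, c.mass * d_tt / max(lls - c.age + d_tt, d_tt))
                c.mass -= dm
                shed_mass += dm
            keep.append(c)
    state.leaves = keep
    litter_struct = 0.0
    prot_loss = 0.0
    if shed_mass > 0.0:
        litter_struct = (1.0 + params.sheath_eff) * shed_mass
        if lam_total > 0.0 and state.w_protein > 0.0:
            prot_loss = min(state.w_protein * shed_mass / lam_total, state.w_protein)
            state.w_protein = max(state.w_protein - prot_loss, 0.0)

    # root turnover
    root_loss = 0.0
    if params.root_lifespan > 0.0:
        root_loss = state.w_root * min(d_tt / params.root_lifespan, 1.0)
        state.w_root -= root_loss

    dead_n = (params.n_struct * (litter_struct + root_loss)
              + params.n_protein * prot_loss)
    remob_n = params.remob_frac * dead_n
    state.substrate.wn += remob_n
    dead_c = params.c_struct * (litter_struct + root_loss) + params.c_protein * prot_loss
    remob_c = params.remob_frac_c * dead_c
    state.substrate.wc += remob_c

    # realized height: erectness rises with population density, capped at the
    # potential height implied by the trait mapping
    max_len = max((c.length(params) for c in state.leaves), default=0.0)
    erect = params.height_shape_factor * (max(state.td, 1.0) / params.td_ref) ** params.height_dens_exp
    h_cap = params.height_shape_factor * params.l0
    state.height = min(erect * max_len, h_cap)

    litter_n = dead_n - remob_n
    return dict(litter_c=dead_c - remob_c, litter_n=litter_n, remob_n=remob_n,
                remob_c=remob_c, litter_mass=litter_struct + root_loss + prot_loss)


def tiller_rate(td: float, s_sub: float, lai: float, params: SpeciesParams) -> float:
    """Net tiller density rate (axes m-2 d-1).

    Apparition is proportional to substrate sufficiency, damped by canopy
    closure and by the remaining site capacity (1 - td/td0); senescence
    (self-thinning) activates above the critical LAI.
    """
    app = (params.tiller_app_rate * td * s_sub
           * max(0.0, 1.0 - lai / params.lai_crit)
           * max(0.0, 1.0 - td / params.td0))
    sen = params.tiller_sen_rate * td * max(0.0, lai / params.lai_crit - 1.0)
    return app - sen


def tiller_dynamics(state: PlantState, params: SpeciesParams, lai: float,
                    s_sub: float = 1.0) -> dict[str, float]:
    """Apply one day of tiller demography, conserving population-level mass.

    Apparition dilutes the average axis (totals unchanged); senescence sends
    the dead axes' structural and protein mass to litter (with N
    remobilisation) while the substrate and reserve pools, shared among
    interconnected tillers, are inherited by the survivors.  Returns per-m2
    litter fluxes.
    """
    td = state.td
    # exact one-day flow of the tiller_rate ODE with frozen coefficients:
    # logistic growth toward td0 below the critical LAI, exponential
    # self-thinning above it (the two regimes are mutually exclusive)
    a_eff = (params.tiller_app_rate * s_sub
             * max(0.0, 1.0 - lai / params.lai_crit))
    b_eff = params.tiller_sen_rate * max(0.0, lai / params.lai_crit - 1.0)
    if a_eff > 0.0 and td < params.td0:
        td_target = params.td0 / (1.0 + (params.td0 / td - 1.0) * math.exp(-a_eff))
        rate = td_target - td
    elif b_eff > 0.0:
        rate = td * (math.exp(-b_eff) - 1.0)
    else:
        rate = 0.0
    litter_c = litter_n = litter_mass = 0.0
    if rate > 0.0:
        td_new = td + rate
        f = td / td_new
        for c in state.leaves:
            c.mass *= f
        state.w_root *= f
        state.w_protein *= f
        state.substrate.wc *= f
        state.substrate.wn *= f
        state.reserves_c *= f
        state.reserves_n *= f
        state.td = td_new
    elif rate < 0.0:
        td_new = max(td + rate, params.td_min)
        d = td - td_new
        if d > 0.0:
            tissue = state.w_shoot(params) + state.w_root
            dead_c = d * (params.c_struct * tissue + params.c_protein * state.w_protein)
            dead_n = d * (params.n_struct * tissue + params.n_protein * state.w_protein)
            remob = params.remob_frac * dead_n
            remob_c = params.remob_frac_c * dead_c
            litter_c = dead_c - remob_c
            litter_n = dead_n - remob
            litter_mass = d * (tissue + state.w_protein)
            # survivors inherit substrates and the remobilised C and N
            f = td / td_new
            state.substrate.wc = state.substrate.wc * f + remob_c / td_new
            state.substrate.wn = state.substrate.wn * f + remob / td_new
            state.reserves_c *= f
            state.reserves_n *= f
            state.td = td_new
    return dict(litter_c=litter_c, litter_n=litter_n, litter_mass=litter_mass)


def apply_management(state: PlantState, event: ManagementEvent,
                     soil_n: float, params: SpeciesParams) -> tuple[float, dict[str, float]]:
    """Apply a cut or fertilisation event.

    Cutting removes, from every lamina whose tip stands above the residual
    height, the fraction of its length above the cut (with the corresponding
    sheath share and protein share); the removed mass is recorded as harvest.
    Fertilisation adds the event magnitude to the mineral soil N pool.
    Returns the updated soil N and per-axis harvest amounts.
    """
    out = dict(harvest_mass=0.0, harvest_c=0.0, harvest_n=0.0)
    if event.kind == "fertilize":
        return soil_n + event.magnitude, out
    # cut
    residual = event.magnitude
    max_len = max((c.length(params) for c in state.leaves), default=0.0)
    if max_len <= 0.0 or state.height <= residual:
        return soil_n, out
    erect = state.height / max_len
    lam_before = state.lamina_mass()
    removed = 0.0
    for c in state.leaves:
        tip = erect * c.length(params)
        if tip > residual:
            frac = (tip - residual) / tip
            dm = frac * c.mass
            c.mass -= dm
            removed += dm
    if removed > 0.0:
        prot_rm = 0.0
        if lam_before > 0.0 and state.w_protein > 0.0:
            prot_rm = min(state.w_protein * removed / lam_before, state.w_protein)
            state.w_protein = max(state.w_protein - prot_rm, 0.0)
        struct_rm = (1.0 + params.sheath_eff) * removed
        out["harvest_mass"] = struct_rm + prot_rm
        out["harvest_c"] = params.c_struct * struct_rm + params.c_protein * prot_rm
        out["harvest_n"] = params.n_struct * struct_rm + params.n_protein * prot_rm
        state.height = min(state.height, residual)
    return soil_n, out


# ---------------------------------------------------------------------------
# daily step and simulation driver
# ---------------------------------------------------------------------------


def initial_state(params: SpeciesParams, soil_n: float = 2.0) -> tuple[PlantState, float]:
    """A small seedling-like state used to start spin-up runs."""
    state = PlantState(
        substrate=SubstratePools(wc=0.004, wn=0.0008),
        alloc=AllocationCoefficients(p=params.p_ref, q=0.3),
        leaves=[LeafCohort(age=0.5 * params.phyllochron, mass=0.2 * params.lamina_mass_max),
                LeafCohort(age=0.0, mass=0.05 * params.lamina_mass_max)],
        w_root=0.01,
        w_protein=0.002,
        td=params.td0,
    )
    return state, soil_n


def step_day(state: PlantState, driver: DailyDriver, events: list[ManagementEvent],
             params: SpeciesParams, soil_n: float) -> tuple[float, dict[str, float]]:
    """Advance the model by one day (mutates ``state``); returns the updated
    soil N pool and the day's ledger fluxes (per m2 ground).

    Process order: management -> interception -> photosynthesis -> uptake ->
    respiration/growth -> substrate balance -> P,Q updates -> morphogenesis ->
    tiller dynamics.
    """
    fx = dict(photo_c=0.0, resp_c=0.0, litter_c=0.0, harvest_c=0.0,
              uptake_n=0.0, litter_n=0.0, harvest_n=0.0,
              fert_n=0.0, mineral_n=0.0, leach_n=0.0,
              growth_mass=0.0, growth_shoot=0.0, growth_root=0.0,
              harvest_mass=0.0, par_int=0.0,
              f_int=0.0, net_photo=0.0, su=0.0, cn=0.0, p=0.0, q=0.0,
              leaf_eff=1.0)
    td = state.td

    # 1. management
    for ev in events:
        if ev.kind == "fertilize":
            fx["fert_n"] += ev.magnitude
        soil_n, h = apply_management(state, ev, soil_n, params)
        fx["harvest_mass"] += h["harvest_mass"] * td
        fx["harvest_c"] += h["harvest_c"] * td
        fx["harvest_n"] += h["harvest_n"] * td

    f_temp = temperature_factor(driver.temp)
    d_tt = max(driver.temp, 0.0)

    # 2. interception (extinction falls with density: denser swards hold
    # their leaves more erect, the "dynamic leaf shape" closure)
    lai = state.lai(params)
    k_eff = params.k_ext * min(max((td / params.td_ref) ** (-params.k_dens_exp), 0.3), 1.5)
    f_int = light_interception(lai, k_eff)
    par_axis = driver.par * f_int / td if td > 0 else 0.0

    # 3-4. photosynthesis and N uptake; canopy aging discounts the usable
    # intercepted light (senescent leaves shade young ones), a cost the
    # coordination loop cannot compensate with extra protein
    leaf_eff = state.leaf_efficiency(params)
    a = photosynthesis(par_axis * leaf_eff, state.w_protein, params, f_temp)
    u = n_uptake(state.w_root, params.sra_eff, soil_n, params.umax, params.km,
                 f_temp, td, params.uptake_cap_frac)

    # 5. growth and respiration (supply/demand with sink caps)
    pools_in = SubstratePools(state.substrate.wc + a, state.substrate.wn + u)
    g = growth_and_respiration(pools_in, state, params, state.alloc, f_temp, d_tt)

    # storage exchange with reserves: a fraction of the substrate excess over
    # the target stoichiometry is parked; deficits draw reserves back down
    wc_after = pools_in.wc - g["maintenance"] - g["growth_resp"] - g["partitioning_c"]
    wn_after = pools_in.wn - g["partitioning_n"]
    store_c = params.storage_frac * (wc_after - params.cn_target * wn_after)
    store_c = max(-state.reserves_c, min(store_c, max(wc_after, 0.0)))
    store_n = params.storage_frac * (wn_after - wc_after / params.cn_target)
    store_n = max(-state.reserves_n, min(store_n, max(wn_after, 0.0)))

    # 6. substrate balance
    x = params.eps_light * par_axis * leaf_eff
    y = params.amax_protein * state.w_protein * f_temp
    state.substrate = substrate_balance(
        state.substrate,
        dict(photosynthesis=a, respiration=g["maintenance"] + g["growth_resp"],
             partitioning_c=g["partitioning_c"], storage_c=store_c,
             uptake=u, partitioning_n=g["partitioning_n"], storage_n=store_n),
    )
    state.reserves_c += store_c
    state.reserves_n += store_n
    state.w_root += g["g_root"]
    state.w_protein += g["g_protein"]

    # 7. allocation coefficient relaxation
    state.alloc.p = functional_balance_p(state.substrate, params, state.alloc)
    state.alloc.q = coordination_q(x, y, state.alloc, params, state.substrate)

    # 8. morphogenesis (consumes the day's shoot structural growth)
    m = morphogenesis_step(state, d_tt, params, g_shoot=g["g_shoot"])

    # 9. tiller dynamics
    wtot = state.w_axis(params)
    s_sub = 1.0
    if wtot > 0.0:
        wc_, wn_ = state.substrate.wc, state.substrate.wn
        s_sub = (wc_ / (wc_ + params.kc * wtot)) * (wn_ / (wn_ + params.kn * wtot))
    t = tiller_dynamics(state, params, lai, s_sub)

    # soil N balance
    mineral = params.mineralization
    leach = params.leach_frac * soil_n
    soil_n = soil_n + mineral - u * td - leach  # fertiliser already added by apply_management
    if soil_n < 0.0:
        leach += soil_n  # uptake cap keeps this a rounding-level correction
        soil_n = 0.0

    # ledger (per m2; morphogenesis/tiller losses at the densities they occurred)
    fx["photo_c"] = a * td
    fx["resp_c"] = (g["maintenance"] + g["growth_resp"]) * td
    fx["litter_c"] = m["litter_c"] * td + t["litter_c"]
    fx["uptake_n"] = u * td
    fx["litter_n"] = m["litter_n"] * td + t["litter_n"]
    fx["mineral_n"] = mineral
    fx["leach_n"] = leach
    fx["growth_mass"] = (g["g_shoot"] + g["g_root"] + g["g_protein"]) * td
    fx["growth_shoot"] = (g["g_shoot"] + g["g_protein"]) * td
    fx["growth_root"] = g["g_root"] * td
    fx["par_int"] = driver.par * f_int
    fx["f_int"] = f_int
    fx["net_photo"] = (a - g["maintenance"] - g["growth_resp"]) * td
    fx["su"] = u
    fx["cn"] = state.substrate.cn_ratio
    fx["p"] = state.alloc.p
    fx["q"] = state.alloc.q
    fx["leaf_eff"] = leaf_eff

    # sanity
    sub = state.substrate
    if not (sub.wc >= 0.0 and sub.wn >= 0.0 and state.w_root >= 0.0
            and state.w_protein >= 0.0 and state.td > 0.0) or \
            math.isnan(sub.wc + sub.wn + state.w_root + state.td):
        raise SimulationError("negative or NaN state", day=driver.day)
    return soil_n, fx


@dataclass
class Trajectory:
    """Output of :func:`run_simulation`.

    ``years`` holds one record per simulated year (production totals per m2
    and per plant plus season-mean diagnostics); ``daily`` optionally holds
    the day-by-day record; ``totals`` accumulates the ledger fluxes of the
    whole run for conservation checks.
    """

    years: pd.DataFrame
    params: SpeciesParams
    daily: pd.DataFrame | None = None
    totals: dict[str, float] = field(default_factory=dict)
    final_state: PlantState | None = None

    @property
    def mean_annual_production(self) -> float:
        """Mean annual structural biomass production (g per plant per year)."""
        return float(self.years["production_plant"].mean())


def run_simulation(params: SpeciesParams, drivers, schedule: list[ManagementEvent],
                   years: int, state: PlantState | None = None,
                   soil_n: float = 2.0, record_daily: bool = False,
                   check_balance: bool = False) -> Trajectory:
    """Run the model for ``years`` years of 365 days.

    ``drivers`` is a sequence of :class:`DailyDriver` (or a DataFrame with
    columns day, par_MJ_m2, temp_C) covering at least one year; it is repeated
    cyclically.  ``schedule`` lists management events by day of year, applied
    every year.  Fully deterministic.
    """
    drv = _as_drivers(drivers)
    n_drv = len(drv)
    if n_drv < 365:
        raise ValueError("drivers must cover at least one 365-day year")
    events_by_doy: dict[int, list[ManagementEvent]] = {}
    for ev in schedule:
        events_by_doy.setdefault(ev.day, []).append(ev)
    if state is None:
        state, soil_n = initial_state(params, soil_n)

    year_rows = []
    daily_rows = [] if record_daily else None
    totals: dict[str, float] = {}
    c0 = state.plant_c(params) * state.td
    n0 = state.plant_n(params) * state.td
    soil0 = soil_n
    day_index = 0
    season = (90, 270)
    for yr in range(years):
        acc = dict(growth_mass=0.0, growth_shoot=0.0, growth_root=0.0,
                   harvest_mass=0.0, uptake_n=0.0, par_int=0.0)
        diag = dict(cn=0.0, f_int=0.0, net_photo=0.0, su=0.0, p=0.0, q=0.0)
        n_season = 0
        for doy in range(1, 366):
            day_index += 1
            base = drv[(day_index - 1) % n_drv]
            driver = DailyDriver(day=day_index, par=base.par, temp=base.temp)
            if check_balance:
                pc0 = state.plant_c(params) * state.td
                pn0 = state.plant_n(params) * state.td
                s0 = soil_n
            soil_n, fx = step_day(state, driver, events_by_doy.get(doy, []),
                                  params, soil_n)
            if check_balance:
                _check_day_balance(state, params, soil_n, fx, pc0, pn0, s0, day_index)
            for k in acc:
                acc[k] += fx[k]
            if season[0] <= doy <= season[1]:
                for k in diag:
                    diag[k] += fx[k]
                n_season += 1
            for k in ("photo_c", "resp_c", "litter_c", "harvest_c", "uptake_n",
                      "litter_n", "harvest_n", "fert_n", "mineral_n", "leach_n"):
                totals[k] = totals.get(k, 0.0) + fx[k]
            if record_daily:
                daily_rows.append(dict(day=day_index, year=yr + 1, doy=doy,
                                       soil_n=soil_n, td=state.td,
                                       height=state.height, lai=state.lai(params),
                                       wc=state.substrate.wc, wn=state.substrate.wn,
                                       w_shoot=state.w_shoot(params),
                                       w_root=state.w_root,
                                       w_protein=state.w_protein, **fx))
        ppm2 = params.plants_per_m2
        row = dict(year=yr + 1,
                   production_above=acc["growth_shoot"],
                   production_below=acc["growth_root"],
                   production_total=acc["growth_mass"],
                   harvest=acc["harvest_mass"],
                   production_plant=acc["growth_mass"] / ppm2,
                   nue=acc["growth_mass"] / acc["uptake_n"] if acc["uptake_n"] > 0 else 0.0,
                   rue=acc["growth_mass"] / acc["par_int"] if acc["par_int"] > 0 else 0.0,
                   td_end=state.td)
        for k in diag:
            row["mean_" + k] = diag[k] / max(n_season, 1)
        year_rows.append(row)

    totals["plant_c0"] = c0
    totals["plant_n0"] = n0
    totals["soil_n0"] = soil0
    totals["plant_c1"] = state.plant_c(params) * state.td
    totals["plant_n1"] = state.plant_n(params) * state.td
    totals["soil_n1"] = soil_n
    return Trajectory(years=pd.DataFrame(year_rows), params=params,
                      daily=pd.DataFrame(daily_rows) if record_daily else None,
                      totals=totals, final_state=state)


def _check_day_balance(state, params, soil_n, fx, pc0, pn0, s0, day):
    pc1 = state.plant_c(params) * state.td
    pn1 = state.plant_n(params) * state.td
    ref_c = max(abs(pc0), abs(pc1), 1e-6)
    err_c = abs((pc1 - pc0) - (fx["photo_c"] - fx["resp_c"] - fx["litter_c"]
                               - fx["harvest_c"])) / ref_c
    ref_n = max(abs(pn0), abs(pn1), 1e-9)
    err_n = abs((pn1 - pn0) - (fx["uptake_n"] - fx["litter_n"] - fx["harvest_n"])) / ref_n
    err_s = abs((soil_n - s0) - (fx["fert_n"] + fx["mineral_n"] - fx["uptake_n"]
                                 - fx["leach_n"])) / max(abs(s0), 1e-6)
    if max(err_c, err_n, err_s) > 1e-6:
        raise SimulationError(
            f"conservation violated: C {err_c:.2e} N {err_n:.2e} soil {err_s:.2e}",
            day=day)


def conservation_errors(traj: Trajectory) -> dict[str, float]:
    """Relative closure errors of the whole-run C and N ledgers."""
    t = traj.totals
    c_in = t["plant_c0"] + t["photo_c"]
    c_out = t["plant_c1"] + t["resp_c"] + t["litter_c"] + t["harvest_c"]
    n_in = t["plant_n0"] + t["uptake_n"]
    n_out = t["plant_n1"] + t["litter_n"] + t["harvest_n"]
    s_in = t["soil_n0"] + t["fert_n"] + t["mineral_n"]
    s_out = t["soil_n1"] + t["uptake_n"] + t["leach_n"]
    return dict(c=abs(c_in - c_out) / max(c_in, 1e-9),
                n=abs(n_in - n_out) / max(n_in, 1e-9),
                soil_n=abs(s_in - s_out) / max(s_in, 1e-9))


def performance(traj: Trajectory) -> float:
    """Mean annual structural biomass production (g per plant per year).

    Arithmetic mean over simulated years of total (above- plus belowground)
    structural growth, which includes mass later removed by cutting, scaled
    to the average plant by the nominal planting density.
    """
    if traj.years is None or len(traj.years) == 0:
        raise ValueError("trajectory contains no complete year")
    return traj.mean_annual_production


def _as_drivers(drivers) -> list[DailyDriver]:
    if isinstance(drivers, pd.DataFrame):
        return [DailyDriver(day=int(r.day), par=float(r.par_MJ_m2), temp=float(r.temp_C))
                for r in drivers.itertuples()]
    return list(drivers)
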