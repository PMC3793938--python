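"""Species parameters, the four manipulated traits, and the trait-to-parameter mapping.

The simulator is parameterised by a :class:`SpeciesParams` record.  Four of its
entries are simple functions of the four functional traits that the virtual
experiment manipulates (specific leaf area, potential plant height, leaf
lifespan and initial tiller density); :func:`map_traits_to_params` applies that
mapping so a trait grid can be swept without touching the rest of the
parameter set.

Trait-parameter mapping
-----------------------
* SLA (cm2 g-1) -> leaf dry-matter content, ``ldmc = 1 / (sla * leaf_thickness * rho)``
  with fresh tissue density ``rho`` fixed at 1 g cm-3 and a constant leaf
  thickness per species.
* H (cm) -> potential mature leaf length ``l0 = h / height_shape_factor``.
* LLS (deg C day) -> phyllochron ``= lls / n_leaves_alive`` (leaf lifespan and
  phyllochron covary tightly in grasses; the number of live leaves per tiller
  is treated as a species constant).
* TD0 (tillers m-2) is the initial (and potential) value of the tiller density
  state variable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import cached_property
from importlib import resources

import pandas as pd

__all__ = [
    "TraitVector",
    "SpeciesParams",
    "TraitValidationError",
    "map_traits_to_params",
    "traits_from_params",
    "load_species_table",
    "DEFAULT_PARAMS",
]

#: Fresh tissue density used in the SLA <-> LDMC conversion (g cm-3).
TISSUE_DENSITY = 1.0

SLA_RANGE = (50.0, 500.0)
LLS_RANGE = (100.0, 1500.0)


class TraitValidationError(ValueError):
    """Raised when a trait vector violates its physical bounds."""


@dataclass(frozen=True)
class TraitVector:
    """The four manipulated functional traits of one grass species.

    Attributes
    ----------
    sla : float
        Specific leaf area, leaf area per leaf dry mass (cm2 g-1).
    h : float
        Potential plant height (cm).
    lls : float
        Leaf lifespan in thermal time (deg C day).
    td0 : float
        Initial/potential tiller density (tillers m-2).
    """

    sla: float
    h: float
    lls: float
    td0: float

    def __post_init__(self) -> None:
        for name in ("sla", "h", "lls", "td0"):
            v = getattr(self, name)
            if not (v > 0):
                raise TraitValidationError(f"trait {name!r} must be strictly positive, got {v!r}")
        if not (SLA_RANGE[0] <= self.sla <= SLA_RANGE[1]):
            raise TraitValidationError(f"sla={self.sla} outside plausible range {SLA_RANGE}")
        if not (LLS_RANGE[0] <= self.lls <= LLS_RANGE[1]):
            raise TraitValidationError(f"lls={self.lls} outside plausible range {LLS_RANGE}")

    def as_dict(self) -> dict[str, float]:
        return {"sla": self.sla, "h": self.h, "lls": self.lls, "td0": self.td0}


@dataclass(frozen=True)
class SpeciesParams:
    """Full parameter set of the average-plant simulator.

    The first four entries are the trait-mapped parameters; everything else is
    either measured species physiology or a structural closure of this model.
    Units are stated per field.
    """

    # --- trait-mapped morphology -------------------------------------------------
    ldmc: float = 0.20          # leaf dry-matter content (g g-1)
    l0: float = 23.0            # potential mature lamina length (cm)
    phyllochron: float = 146.0  # thermal time between leaf appearances (deg C day)
    td0: float = 4879.0         # initial/potential tiller density (tillers m-2)

    # --- shoot geometry ----------------------------------------------------------
    leaf_thickness: float = 0.022   # lamina thickness (cm)
    sheath_ratio: float = 0.6       # sheath:lamina mass ratio (dimensionless)
    form_factor: float = 0.7        # lamina area / (length * width)
    leaf_width_frac: float = 0.012  # lamina width as a fraction of l0
    height_shape_factor: float = 2.0  # potential height / potential lamina length
    height_dens_exp: float = 0.10   # erectness increase with tiller density
    k_dens_exp: float = 0.0         # extinction decrease with tiller density
    td_ref: float = 5000.0          # reference tiller density for shape laws (m-2)
    n_leaves_alive: float = 3.0     # live leaves per tiller = lls / phyllochron
    expand_phyllochrons: float = 1.5  # lamina expansion duration in phyllochrons
    sen_window_frac: float = 0.25   # fraction of lls over which a leaf sheds gradually

    # --- tissue chemistry ----------------------------------------------------------
    c_struct: float = 0.45      # C fraction of structural tissue (gC g-1)
    n_struct: float = 0.015     # N fraction of structural tissue (gN g-1)
    c_protein: float = 0.53     # C fraction of photosynthetic protein (gC g-1)
    n_protein: float = 0.16     # N fraction of photosynthetic protein (gN g-1)

    # --- physiology ----------------------------------------------------------------
    amax_protein: float = 10.0  # photosynthetic capacity per protein mass (gC gProt-1 d-1)
    eps_light: float = 2.4      # light-limited conversion (gC MJ-1 PAR intercepted)
    k_ext: float = 0.8         # canopy extinction coefficient (dimensionless)
    protein_frac_max: float = 0.25  # max protein per lamina structural mass (g g-1)
    umax: float = 0.06          # N uptake per root area (gN m-2 root d-1)
    km: float = 1.5             # uptake half-saturation (gN m-2 soil)
    sra: float = 0.12           # specific root area (m2 g-1)
    root_max_length: float = 40.0   # fine root maximum length (cm)
    root_lifespan: float = 600.0    # fine root lifespan (deg C day)
    root_mass_per_cm: float = 0.005  # axis root mass per cm of max root length (g cm-1)
    root_lifespan_ref: float = 600.0  # reference lifespan for the area/longevity trade-off
    r_maint: float = 0.008      # maintenance respiration (gC gDM-1 d-1 at 20 deg C, at sla_ref)
    sla_ref: float = 230.0      # reference SLA for the respiration-SLA scaling (cm2 g-1)
    resp_sla_exp: float = 1.2   # specific respiration rises with SLA (cheap tissue respires more)
    l0_ref: float = 23.0        # reference lamina length for the sheath allometry (cm)
    sheath_h_exp: float = 0.9   # sheath share rises with lamina length (support allometry)
    r_axis: float = 2.5e-4      # per-axis overhead respiration (gC axis-1 d-1 at 20 deg C)
    tau_leaf: float = 1100.0     # thermal timescale of photosynthetic leaf aging (deg C day)
    y_growth: float = 0.75      # growth yield (g structural C per g substrate C)
    g_max: float = 0.30         # potential relative growth rate (d-1 at 20 deg C)
    kc: float = 0.08            # C substrate half-saturation (gC g-1 structure)
    kn: float = 0.010           # N substrate half-saturation (gN g-1 structure)

    # --- substrate handling -----------------------------------------------------
    remob_frac: float = 0.6    # fraction of senescing-tissue N recycled to substrate
    remob_frac_c: float = 0.2   # fraction of senescing-tissue C recycled to substrate
    cn_target: float = 5.0      # target substrate C:N (gC gN-1)
    storage_frac: float = 0.05  # daily fraction of substrate excess moved to reserves
    p_min: float = 0.15         # lower bound on root allocation fraction
    p_max: float = 0.75         # upper bound on root allocation fraction
    p_ref: float = 0.35         # root allocation at substrate C:N = target
    tau_p: float = 5.0          # relaxation time of P (d)
    tau_q: float = 10.0         # relaxation time of Q (d)
    q_stoich: float = 0.5       # stoichiometric damping of Q by substrate C:N excess
    smooth_theta: float = 0.95  # curvature of the smooth-min photosynthesis closure

    # --- demography ----------------------------------------------------------------
    tiller_app_rate: float = 0.04   # tiller apparition rate (d-1)
    tiller_sen_rate: float = 0.04   # tiller senescence rate (d-1)
    lai_crit_frac: float = 0.75     # self-thinning LAI as a fraction of the
                                    # species' geometric canopy capacity
    td_min: float = 10.0            # floor on tiller density (m-2)

    # --- environment couplers ----------------------------------------------------
    mineralization: float = 0.015   # background soil N mineralisation (gN m-2 d-1)
    leach_frac: float = 0.02        # daily fractional loss of mineral soil N (d-1)
    uptake_cap_frac: float = 0.5    # max fraction of the soil pool extractable per day
    plants_per_m2: float = 2500.0   # nominal planting density (average plants m-2)

    def replace(self, **kw) -> "SpeciesParams":
        return dataclasses.replace(self, **kw)

    def __post_init__(self) -> None:
        if not (0.0 < self.ldmc < 1.0):
            raise ValueError(f"ldmc must be in (0, 1), got {self.ldmc}")
        if not (0.0 < self.y_growth <= 1.0):
            raise ValueError(f"y_growth must be in (0, 1], got {self.y_growth}")
        if not (self.p_min < self.p_max):
            raise ValueError("p_min must be < p_max")
        for name in ("phyllochron", "l0", "td0", "umax", "km", "sra", "r_maint",
                     "g_max", "tiller_app_rate", "tiller_sen_rate", "lai_crit_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    # Derived geometry -------------------------------------------------------------

    @cached_property
    def sla(self) -> float:
        """Specific leaf area implied by ldmc and thickness (cm2 g-1)."""
        return 1.0 / (self.ldmc * self.leaf_thickness * TISSUE_DENSITY)

    @cached_property
    def lls(self) -> float:
        """Leaf lifespan implied by the phyllochron (deg C day)."""
        return self.phyllochron * self.n_leaves_alive

    @cached_property
    def leaf_width(self) -> float:
        """Lamina width (cm): a species constant set by the observed
        allometry (width tracks the species' own mature leaf length, not the
        swept potential length)."""
        return self.leaf_width_frac * self.l0_ref

    @cached_property
    def lamina_area_max(self) -> float:
        """Potential area of one mature lamina (cm2)."""
        return self.form_factor * self.l0 * self.leaf_width

    @cached_property
    def lamina_mass_max(self) -> float:
        """Potential structural mass of one mature lamina (g)."""
        return self.lamina_area_max / self.sla

    @cached_property
    def sheath_eff(self) -> float:
        """Effective sheath:lamina mass ratio; longer leaves need more support."""
        return self.sheath_ratio * (self.l0 / self.l0_ref) ** self.sheath_h_exp

    @cached_property
    def lai_crit(self) -> float:
        """Self-thinning critical LAI (m2 m-2).

        A fixed fraction of the species' own canopy packing capacity
        (reference stand density x live leaves x mature lamina area at the
        observed geometry): each species self-thins relative to the canopy
        it is adapted to, not to a universal constant.
        """
        area_ref = self.form_factor * self.l0_ref * self.leaf_width  # cm2
        return self.lai_crit_frac * self.td_ref * self.n_leaves_alive * area_ref * 1e-4

    @cached_property
    def r_axis_eff(self) -> float:
        """Per-axis overhead respiration (gC axis-1 d-1).

        Dense-tillering species have proportionally smaller axes with
        cheaper apex/pseudostem upkeep, so the overhead scales inversely
        with the species' reference stand density.
        """
        return self.r_axis * 5000.0 / self.td_ref

    @cached_property
    def r_maint_eff(self) -> float:
        """Maintenance respiration adjusted for tissue construction (gC gDM-1 d-1).

        High-SLA (low-LDMC) tissue is metabolically more active per dry gram.
        """
        return self.r_maint * (self.sla / self.sla_ref) ** self.resp_sla_exp

    @cached_property
    def w_root_max(self) -> float:
        """Maximum fine-root structural mass per axis (g)."""
        return self.root_max_length * self.root_mass_per_cm

    @cached_property
    def sra_eff(self) -> float:
        """Effective specific root area; longer-lived roots are coarser (m2 g-1)."""
        return self.sra * (self.root_lifespan_ref / self.root_lifespan) ** 0.5


DEFAULT_PARAMS = SpeciesParams()


def map_traits_to_params(traits: TraitVector, base: SpeciesParams) -> SpeciesParams:
    """Return a copy of ``base`` with the four trait-mapped parameters replaced.

    Only ldmc, l0, phyllochron and td0 change; every other parameter of
    ``base`` is untouched, which is what makes the factorial trait sweep a
    controlled experiment.
    """
    if not isinstance(traits, TraitVector):
        traits = TraitVector(**traits)  # raises TraitValidationError on bad input
    return base.replace(
        ldmc=1.0 / (traits.sla * base.leaf_thickness * TISSUE_DENSITY),
        l0=traits.h / base.height_shape_factor,
        phyllochron=traits.lls / base.n_leaves_alive,
        td0=traits.td0,
    )


def traits_from_params(params: SpeciesParams) -> TraitVector:
    """Invert the trait mapping (used for round-trip checks and reporting)."""
    return TraitVector(
        sla=params.sla,
        h=params.l0 * params.height_shape_factor,
        lls=params.lls,
        td0=params.td0,
    )


def load_species_table() -> pd.DataFrame:
    """Load the packaged 12-species table of field-derived optimal traits.

    Columns: species, code, sla_cm2_g, h_cm, lls_Cday, td_m2, cn_opt_gC_gN.
    These are the high-N optimum trait values and optimal substrate C:N of the
    12 perennial C3 grasses the model family was calibrated on.
    """
    with resources.files("gramscape.data").joinpath("species_traits.csv").open() as fh:
        return pd.read_csv(fh, comment="#")
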