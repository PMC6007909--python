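"""Proximate and ultimate ecological impact equations.

The framework estimates the impact of a proposed scientific activity inside
a protected area at three levels:

* **population** -- the targeted species, when one is declared;
* **assemblage** -- each of four macro-organism assemblages (macrophytes,
  sessile invertebrates, mobile invertebrates, fishes), tracked separately
  and never summed across assemblages;
* **habitat** -- each physical habitat class touched by the activity.

Each level yields a *proximate impact* (PI), the proportion of the entity
within the MPA directly affected, and an *ultimate impact* (UI), the
proximate impact extended through time and the food web:

    PI_pop   = {M + (1 - M) * M_hand} * (1 / Eff) * N / (Dens * A_MPA)
    UI_pop   = PI * (RT / 2) * Interaction
    PI_assemb = {M + (1 - M) * M_hand_nontarg} * Suscep * A_samp / A_MPA
    UI_assemb = PI * (RT / 2) * Interaction
    PI_hab   = P_alt * A_samp / A_MPA
    UI_hab   = PI * (RT / 2)

RT/2 encodes an assumed linear recovery from the moment of impact to full
recovery after RT years; the interaction index (>= 1) encodes the
ecological role of the species or assemblage.  Habitat UI carries no
interaction index -- all physical habitat is considered vitally important
-- and habitat recovery time is capped at 20 years at construction.

Proximate impacts are proportions and are clamped to [0, 1] with a
:class:`ImpactClampWarning`; ultimate impacts are unitless and unbounded
above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class OrganismGroup(str, Enum):
    """Organism groups used for method-mortality lookup.

    ``FISHES_WITH_SWIM_BLADDER`` is a refinement of ``FISHES`` that exists
    only so that pressure-related (barotrauma) mortality can be assigned to
    physoclistous fishes; for susceptibility and assemblage accounting it
    falls back to the fish assemblage.
    """

    MACROPHYTES = "macrophytes"
    SESSILE_INVERTEBRATES = "sessile_invertebrates"
    MOBILE_INVERTEBRATES = "mobile_invertebrates"
    FISHES = "fishes"
    FISHES_WITH_SWIM_BLADDER = "fishes_with_swim_bladder"


#: The four assemblages whose impacts are tracked separately.
ASSEMBLAGES: tuple[str, ...] = (
    "macrophytes",
    "sessile_invertebrates",
    "mobile_invertebrates",
    "fishes",
)


def assemblage_of(group: OrganismGroup | str) -> str:
    """Assemblage a group belongs to (swim-bladder fishes -> fishes)."""
    group = OrganismGroup(group)
    if group is OrganismGroup.FISHES_WITH_SWIM_BLADDER:
        return "fishes"
    return group.value


class ModelInputError(ValueError):
    """A model input violates its domain (range, missing key, zero divisor)."""


class ImpactClampWarning(UserWarning):
    """A proportion exceeded 1 and was clamped."""


def _check_proportion(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ModelInputError(f"{name} must be in [0, 1], got {value}")
    return float(value)


def _clamp_proportion(value: float, what: str) -> float:
    if value > 1.0:
        warnings.warn(
            f"{what} = {value:.6g} exceeds 1; clamped to 1 "
            "(proposed take exceeds the estimated available amount)",
            ImpactClampWarning,
            stacklevel=3,
        )
        return 1.0
    return value


@dataclass(frozen=True)
class MethodProfile:
    """Per-method impact parameters.

    mortality_by_group
        M_meth: proportionate mortality inflicted by the method on each
        organism group it can affect.
    susceptibility_by_assemblage
        Suscep_meth: proportion of each assemblage, within the sampled
        area, vulnerable to take by the method.  Every assemblage the
        caller asks about must be present -- a missing key is an input
        error, never an implicit zero.
    habitat_alteration_by_class
        P_alt: probability (0-1) that the method alters each habitat class.
    """

    method_id: str
    mortality_by_group: Mapping[OrganismGroup | str, float] = field(default_factory=dict)
    susceptibility_by_assemblage: Mapping[str, float] = field(default_factory=dict)
    habitat_alteration_by_class: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "mortality_by_group",
            {
                OrganismGroup(g): _check_proportion(f"mortality[{g}]", v)
                for g, v in self.mortality_by_group.items()
            },
        )
        for a, v in self.susceptibility_by_assemblage.items():
            if a not in ASSEMBLAGES:
                raise ModelInputError(f"unknown assemblage {a!r}")
            _check_proportion(f"susceptibility[{a}]", v)
        for h, v in self.habitat_alteration_by_class.items():
            _check_proportion(f"p_alt[{h}]", v)

    def mortality_for(self, group: OrganismGroup | str) -> float:
        group = OrganismGroup(group)
        try:
            return self.mortality_by_group[group]
        except KeyError:
            raise ModelInputError(
                f"method {self.method_id!r} has no mortality for group "
                f"{group.value!r}"
            ) from None

    def susceptibility_for(self, assemblage: str) -> float:
        try:
            return self.susceptibility_by_assemblage[assemblage]
        except KeyError:
            raise ModelInputError(
                f"method {self.method_id!r} has no susceptibility for "
                f"assemblage {assemblage!r}"
            ) from None

    def alteration_for(self, habitat_class: str) -> float:
        try:
            return self.habitat_alteration_by_class[habitat_class]
        except KeyError:
            raise ModelInputError(
                f"method {self.method_id!r} has no habitat-alteration "
                f"probability for {habitat_class!r}"
            ) from None


@dataclass(frozen=True)
class HandlingSpec:
    """Handling mortality and method efficacy for one project component.

    efficacy
        Eff_meth: proportionate success of the method, i.e. the fraction of
        handled organisms that actually serve the study (N_targ / total
        collected).  Strictly positive: a method that never succeeds takes
        nothing, but the impact equation is undefined at Eff = 0, so the
        caller must model such a procedure differently.
    """

    mortality_target: float = 0.0
    mortality_nontarget: float = 0.0
    efficacy: float = 1.0

    def __post_init__(self) -> None:
        _check_proportion("mortality_target", self.mortality_target)
        _check_proportion("mortality_nontarget", self.mortality_nontarget)
        if not 0.0 < self.efficacy <= 1.0:
            raise ModelInputError(
                f"efficacy must be in (0, 1], got {self.efficacy}"
            )


@dataclass(frozen=True)
class TargetSpec:
    """A declared target: what is taken and how abundant it is.

    ``n_target`` and ``abundance_density`` must share abundance units:
    individuals and individuals/m^2 for countable taxa, or absolute cover
    area (m^2) and cover-area per m^2 for cover-based taxa, which keeps the
    N / (Dens * A) ratio dimensionless either way.
    """

    species_id: str
    n_target: float
    abundance_density: float
    habitat_class: str

    def __post_init__(self) -> None:
        if self.n_target < 0:
            raise ModelInputError(f"n_target must be >= 0, got {self.n_target}")
        if self.abundance_density < 0:
            raise ModelInputError(
                f"abundance_density must be >= 0, got {self.abundance_density}"
            )
        if self.n_target > 0 and self.abundance_density <= 0:
            raise ModelInputError(
                f"target {self.species_id!r}: positive take requires a "
                "positive abundance density"
            )


class FootprintProvenance(str, Enum):
    DECLARED_PLOTS = "declared_plots"
    INFERRED_FROM_TARGET = "inferred_from_target"


@dataclass(frozen=True)
class SamplingFootprint:
    """Area of habitat subject to sampling (A_samp_hab, m^2)."""

    area_sampled_m2: float
    provenance: FootprintProvenance
    inefficiency_scalar: float = 5.0

    def __post_init__(self) -> None:
        if self.area_sampled_m2 < 0:
            raise ModelInputError(
                f"sampled area must be >= 0, got {self.area_sampled_m2}"
            )
        if self.inefficiency_scalar < 1:
            raise ModelInputError(
                f"inefficiency scalar must be >= 1, got {self.inefficiency_scalar}"
            )

    @property
    def occupied_area_m2(self) -> float:
        """Area the targeted organisms themselves occupy (footprint without
        the sampling-inefficiency magnification)."""
        return self.area_sampled_m2 / self.inefficiency_scalar


#: Habitat recovery beyond this horizon is treated as 20 years for
#: pragmatic cumulative accounting (longer-lasting alterations warrant
#: case-by-case scrutiny instead).
HABITAT_RT_CAP_Y = 20.0


@dataclass(frozen=True)
class HabitatParams:
    """Area and recovery time of one habitat class within the MPA.

    ``recovery_time_y`` is capped at 20 years at construction.
    """

    habitat_class: str
    area_mpa_m2: float
    recovery_time_y: float

    def __post_init__(self) -> None:
        if self.area_mpa_m2 <= 0:
            raise ModelInputError(
                f"habitat {self.habitat_class!r}: MPA area must be > 0"
            )
        if self.recovery_time_y <= 0:
            raise ModelInputError(
                f"habitat {self.habitat_class!r}: recovery time must be > 0"
            )
        object.__setattr__(
            self, "recovery_time_y", min(float(self.recovery_time_y), HABITAT_RT_CAP_Y)
        )


@dataclass(frozen=True)
class VulnerabilityParams:
    """Recovery time (years) and interaction index (>= 1) of a species or
    assemblage.  RT = 2 with index 1 is the neutral scaling: UI equals PI."""

    recovery_time_y: float
    interaction_index: float = 1.0

    def __post_init__(self) -> None:
        if self.recovery_time_y <= 0:
            raise ModelInputError(
                f"recovery time must be > 0, got {self.recovery_time_y}"
            )
        if self.interaction_index < 1:
            raise ModelInputError(
                f"interaction index must be >= 1, got {self.interaction_index}"
            )


@dataclass
class ImpactResult:
    """Proximate and ultimate impacts of one project.

    Population entries are present only when a target was declared.
    Assemblage impacts are per assemblage and are never summed across
    assemblages anywhere in the package.
    """

    pi_population: dict[str, float] | None = None
    ui_population: dict[str, float] | None = None
    pi_by_assemblage: dict[str, float] = field(default_factory=dict)
    ui_by_assemblage: dict[str, float] = field(default_factory=dict)
    pi_by_habitat: dict[str, float] = field(default_factory=dict)
    ui_by_habitat: dict[str, float] = field(default_factory=dict)

    def ultimate_by_entity(self) -> dict[tuple[str, str], float]:
        """Flatten ultimate impacts to {(level, entity_id): UI}."""
        out: dict[tuple[str, str], float] = {}
        if self.ui_population:
            for sp, ui in self.ui_population.items():
                out[("population", sp)] = ui
        for a, ui in self.ui_by_assemblage.items():
            out[("assemblage", a)] = ui
        for h, ui in self.ui_by_habitat.items():
            out[("habitat", h)] = ui
        return out

    def max_ultimate(self) -> float:
        entities = self.ultimate_by_entity()
        return max(entities.values()) if entities else 0.0


# ---------------------------------------------------------------------------
# The seven impact operations
# ---------------------------------------------------------------------------

def proximate_population_impact(
    method: MethodProfile,
    group: OrganismGroup | str,
    handling: HandlingSpec,
    target: TargetSpec,
    habitat: HabitatParams,
) -> float:
    """Proportion of the target population within the MPA killed by the
    proposed activity (PI_targ).

    Combines method mortality M, handling mortality applied to survivors
    (1 - M) * M_hand, inflation by limited efficacy 1/Eff, and the share of
    the population taken, N / (Dens * A_MPA).  Clamped to 1 with a warning
    when the proposed take exceeds the estimated population.
    """
    if target.habitat_class != habitat.habitat_class:
        raise ModelInputError(
            f"target habitat {target.habitat_class!r} does not match "
            f"habitat parameters for {habitat.habitat_class!r}"
        )
    if target.n_target == 0:
        return 0.0
    population = target.abundance_density * habitat.area_mpa_m2
    if population <= 0:
        raise ModelInputError(
            f"target {target.species_id!r}: estimated population is zero "
            "(density x habitat area); a positive take cannot be assessed"
        )
    m = method.mortality_for(group)
    lethal = m + (1.0 - m) * handling.mortality_target
    pi = lethal * (1.0 / handling.efficacy) * target.n_target / population
    return _clamp_proportion(pi, f"PI_population[{target.species_id}]")


def ultimate_population_impact(pi: float, vuln: VulnerabilityParams) -> float:
    """UI_targ = PI * (RT / 2) * Interaction (unitless, unbounded above)."""
    _check_proportion("pi", pi)
    return pi * (vuln.recovery_time_y / 2.0) * vuln.interaction_index


def sampled_area_from_target(
    target: TargetSpec, scalar: float = 5.0
) -> SamplingFootprint:
    """Infer the sampled area from the target take and its density.

    A_samp = (N / Dens) * scalar.  N / Dens is the area the targeted
    organisms occupy; the ad-hoc inefficiency scalar (default 5) magnifies
    it to the area that realistically must be worked to obtain them, and
    can be replaced when better information exists.
    """
    if scalar < 1:
        raise ModelInputError(f"inefficiency scalar must be >= 1, got {scalar}")
    if target.n_target == 0:
        return SamplingFootprint(0.0, FootprintProvenance.INFERRED_FROM_TARGET, scalar)
    if target.abundance_density <= 0:
        raise ModelInputError(
            f"target {target.species_id!r}: cannot infer sampled area from "
            "zero abundance density"
        )
    area = target.n_target / target.abundance_density * scalar
    return SamplingFootprint(area, FootprintProvenance.INFERRED_FROM_TARGET, scalar)


def sampled_area_from_plots(
    plot_area_m2: float,
    n_plots: int,
    n_events: int,
    new_plots_each_event: bool,
) -> SamplingFootprint:
    """Sampled area of an explicit plot design.

    Repeated sampling of the *same* plots does not increase the affected
    area, so only designs laying out new plots each event multiply by the
    number of events.
    """
    if plot_area_m2 < 0 or n_plots < 0 or n_events < 0:
        raise ModelInputError("plot area and counts must be >= 0")
    if new_plots_each_event:
        area = plot_area_m2 * n_plots * n_events
    else:
        area = plot_area_m2 * n_plots * (1 if n_events > 0 else 0)
    return SamplingFootprint(area, FootprintProvenance.DECLARED_PLOTS, 1.0)


def _area_fraction(footprint: SamplingFootprint, habitat: HabitatParams, what: str) -> float:
    return _clamp_proportion(footprint.area_sampled_m2 / habitat.area_mpa_m2, what)


def proximate_assemblage_impact(
    method: MethodProfile,
    assemblage: str,
    handling: HandlingSpec,
    footprint: SamplingFootprint,
    habitat: HabitatParams,
) -> float:
    """Proportion of an assemblage within the MPA killed, directly or
    incidentally (PI_assemb).

    Assumes the assemblage is uniformly distributed over its habitat, so
    the fraction encountered equals A_samp / A_MPA (clamped to 1); of those,
    the susceptible fraction Suscep suffers method mortality and, for
    survivors, non-target handling mortality.
    """
    if assemblage not in ASSEMBLAGES:
        raise ModelInputError(f"unknown assemblage {assemblage!r}")
    suscep = method.susceptibility_for(assemblage)
    m = method.mortality_for(assemblage)
    lethal = m + (1.0 - m) * handling.mortality_nontarget
    frac = _area_fraction(footprint, habitat, f"A_samp/A_MPA[{assemblage}]")
    return lethal * suscep * frac


def ultimate_assemblage_impact(pi: float, vuln: VulnerabilityParams) -> float:
    """UI_assemb = PI * (RT / 2) * Interaction."""
    return ultimate_population_impact(pi, vuln)


def proximate_habitat_impact(
    method: MethodProfile,
    habitat_class: str,
    footprint: SamplingFootprint,
    habitat: HabitatParams,
) -> float:
    """Proportion of a habitat class within the MPA altered (PI_hab):
    P_alt * A_samp / A_MPA, with the area ratio clamped to 1."""
    p_alt = method.alteration_for(habitat_class)
    frac = _area_fraction(footprint, habitat, f"A_samp/A_MPA[{habitat_class}]")
    return p_alt * frac


def ultimate_habitat_impact(pi: float, habitat: HabitatParams) -> float:
    """UI_hab = PI * (RT / 2).

    No interaction index: all physical habitat is treated as vitally
    important to its inhabitants, so habitat UI is modified by recovery
    time only.  The stored RT is already capped at 20 years.
    """
    _check_proportion("pi", pi)
    return pi * (habitat.recovery_time_y / 2.0)


def max_allowable_proximate_impact(
    ui_threshold: float, vuln: VulnerabilityParams
) -> float:
    """Largest proximate impact whose ultimate impact stays at the
    threshold: the exact inverse of the UI scaling, clamped to 1.

    With the default threshold of 0.1 this corresponds to extracting at
    most 10% of the population of a short-lived (RT = 2 y), ecologically
    neutral (index 1) species, and far less for slow-recovering strong
    interactors.
    """
    if ui_threshold <= 0:
        raise ModelInputError(f"threshold must be > 0, got {ui_threshold}")
    pi = ui_threshold / ((vuln.recovery_time_y / 2.0) * vuln.interaction_index)
    return min(pi, 1.0)
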