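"""Project evaluation, cumulative ledger, and threshold comparison.

A proposal is decomposed into components (one target/method/effort unit
each); each component is run through the population (if a target is
declared), assemblage, and habitat models; impacts are summed within each
entity -- a species' population, one of the four assemblages, a habitat
class -- and never across assemblages.  Ultimate impacts of the candidate
are added to those of all still-unrecovered permitted projects in the
ledger and compared against the policy thresholds to produce a
recommendation.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import core
from .core import (
    ASSEMBLAGES,
    HandlingSpec,
    HabitatParams,
    ImpactClampWarning,
    ImpactResult,
    MethodProfile,
    ModelInputError,
    OrganismGroup,
    TargetSpec,
    VulnerabilityParams,
)

EntityKey = tuple[str, str]  # (level, entity id) e.g. ("assemblage", "fishes")

_DAYS_PER_YEAR = 365.2425


# ---------------------------------------------------------------------------
# Proposal structure and parameter bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetRef:
    species_id: str
    n_target: float


@dataclass(frozen=True)
class PlotSchedule:
    plot_area_m2: float
    n_plots: int
    n_events: int = 1
    new_plots_each_event: bool = False


@dataclass(frozen=True)
class ProjectComponent:
    """One target/method/effort unit of a proposal.

    Effort is either an explicit plot schedule or, when absent, inferred
    from the target's take and density; a component with neither a target
    nor plots has no defined footprint and is rejected.  A component
    without a target skips the population model entirely.
    """

    method_id: str
    habitat_class: str
    handling: HandlingSpec = HandlingSpec()
    target: TargetRef | None = None
    plots: PlotSchedule | None = None

    def __post_init__(self) -> None:
        if self.target is None and self.plots is None:
            raise ModelInputError(
                "a component needs either a declared target (to infer its "
                "footprint) or an explicit plot schedule"
            )


@dataclass(frozen=True)
class SpeciesParams:
    """Per-MPA parameters for one species."""

    species_id: str
    assemblage: str
    habitat_class: str
    density_per_m2: float
    recovery_time_y: float
    interaction_index: float = 1.0
    group: OrganismGroup | None = None  # mortality-lookup group; defaults to assemblage

    def __post_init__(self) -> None:
        if self.assemblage not in ASSEMBLAGES:
            raise ModelInputError(
                f"species {self.species_id!r}: unknown assemblage "
                f"{self.assemblage!r}"
            )
        group = self.assemblage if self.group is None else self.group
        object.__setattr__(self, "group", OrganismGroup(group))

    @property
    def vulnerability(self) -> VulnerabilityParams:
        return VulnerabilityParams(self.recovery_time_y, self.interaction_index)


@dataclass
class ParameterBundle:
    """Everything needed to evaluate proposals against one MPA."""

    mpa_id: str
    methods: dict[str, MethodProfile]
    species: dict[str, SpeciesParams]
    assemblage_vulnerability: dict[str, VulnerabilityParams]
    habitats: dict[str, HabitatParams]


def _resolve(bundle: ParameterBundle, components: Sequence[ProjectComponent]) -> None:
    missing: list[str] = []
    for i, c in enumerate(components):
        if c.method_id not in bundle.methods:
            missing.append(f"component {i}: method {c.method_id!r}")
        if c.habitat_class not in bundle.habitats:
            missing.append(f"component {i}: habitat {c.habitat_class!r}")
        if c.target is not None and c.target.species_id not in bundle.species:
            missing.append(f"component {i}: species {c.target.species_id!r}")
    for a in ASSEMBLAGES:
        if a not in bundle.assemblage_vulnerability:
            missing.append(f"assemblage vulnerability for {a!r}")
    if missing:
        raise ModelInputError(
            "unresolvable parameter references:\n  " + "\n  ".join(missing)
        )


# ---------------------------------------------------------------------------
# Project evaluation
# ---------------------------------------------------------------------------

def evaluate_project(
    components: Sequence[ProjectComponent], bundle: ParameterBundle
) -> ImpactResult:
    """Evaluate every component and sum impacts within each entity.

    The population model runs only for components with a declared target;
    the assemblage model runs for all four assemblages of every component;
    the habitat model runs for each touched habitat class.  Summed
    proximate impacts are clamped to 1 (with a warning) since they remain
    proportions.
    """
    _resolve(bundle, components)

    pi_pop: dict[str, float] = {}
    ui_pop: dict[str, float] = {}
    pi_asm: dict[str, float] = {a: 0.0 for a in ASSEMBLAGES}
    ui_asm: dict[str, float] = {a: 0.0 for a in ASSEMBLAGES}
    pi_hab: dict[str, float] = {}
    ui_hab: dict[str, float] = {}
    any_target = False

    for c in components:
        method = bundle.methods[c.method_id]
        habitat = bundle.habitats[c.habitat_class]

        target_spec: TargetSpec | None = None
        if c.target is not None:
            sp = bundle.species[c.target.species_id]
            target_spec = TargetSpec(
                species_id=sp.species_id,
                n_target=c.target.n_target,
                abundance_density=sp.density_per_m2,
                habitat_class=sp.habitat_class,
            )

        if c.plots is not None:
            footprint = core.sampled_area_from_plots(
                c.plots.plot_area_m2,
                c.plots.n_plots,
                c.plots.n_events,
                c.plots.new_plots_each_event,
            )
        else:
            assert target_spec is not None
            footprint = core.sampled_area_from_target(target_spec)

        if target_spec is not None:
            any_target = True
            sp = bundle.species[c.target.species_id]
            pi = core.proximate_population_impact(
                method, sp.group, c.handling, target_spec, habitat
            )
            ui = core.ultimate_population_impact(pi, sp.vulnerability)
            pi_pop[sp.species_id] = pi_pop.get(sp.species_id, 0.0) + pi
            ui_pop[sp.species_id] = ui_pop.get(sp.species_id, 0.0) + ui

        for a in ASSEMBLAGES:
            pi = core.proximate_assemblage_impact(
                method, a, c.handling, footprint, habitat
            )
            ui = core.ultimate_assemblage_impact(
                pi, bundle.assemblage_vulnerability[a]
            )
            pi_asm[a] += pi
            ui_asm[a] += ui

        pi = core.proximate_habitat_impact(
            method, c.habitat_class, footprint, habitat
        )
        ui = core.ultimate_habitat_impact(pi, habitat)
        pi_hab[c.habitat_class] = pi_hab.get(c.habitat_class, 0.0) + pi
        ui_hab[c.habitat_class] = ui_hab.get(c.habitat_class, 0.0) + ui

    def _clamp_all(d: dict[str, float], level: str) -> dict[str, float]:
        out = {}
        for k, v in d.items():
            if v > 1.0:
                warnings.warn(
                    f"summed proximate {level} impact for {k!r} exceeds 1; "
                    "clamped",
                    ImpactClampWarning,
                    stacklevel=3,
                )
                v = 1.0
            out[k] = v
        return out

    return ImpactResult(
        pi_population=_clamp_all(pi_pop, "population") if any_target else None,
        ui_population=dict(ui_pop) if any_target else None,
        pi_by_assemblage=_clamp_all(pi_asm, "assemblage"),
        ui_by_assemblage=dict(ui_asm),
        pi_by_habitat=_clamp_all(pi_hab, "habitat"),
        ui_by_habitat=dict(ui_hab),
    )


def evaluate_alternatives(
    alternative_sets: Sequence[Sequence[ProjectComponent]],
    bundle: ParameterBundle,
) -> ImpactResult:
    """Evaluate alternative method sets and keep, per entity, the maximum
    impact -- the most impactful realistic combination governs the
    assessment when the applicant is uncertain which methods will be used.
    """
    if not alternative_sets:
        raise ModelInputError("at least one alternative component set is required")
    results = [evaluate_project(cs, bundle) for cs in alternative_sets]

    def _merge(dicts: list[dict[str, float] | None]) -> dict[str, float] | None:
        present = [d for d in dicts if d is not None]
        if not present:
            return None
        out: dict[str, float] = {}
        for d in present:
            for k, v in d.items():
                out[k] = max(out.get(k, 0.0), v)
        return out

    return ImpactResult(
        pi_population=_merge([r.pi_population for r in results]),
        ui_population=_merge([r.ui_population for r in results]),
        pi_by_assemblage=_merge([r.pi_by_assemblage for r in results]) or {},
        ui_by_assemblage=_merge([r.ui_by_assemblage for r in results]) or {},
        pi_by_habitat=_merge([r.pi_by_habitat for r in results]) or {},
        ui_by_habitat=_merge([r.ui_by_habitat for r in results]) or {},
    )


# ---------------------------------------------------------------------------
# Cumulative ledger
# ---------------------------------------------------------------------------

@dataclass
class LedgerEntry:
    """A permitted project's impact record.

    Each impacted entity carries an expiry date -- impact date plus that
    entity's recovery time -- after which the entry no longer counts
    against the cumulative budget (step expiry: the full ultimate impact is
    retained until recovery is complete, then drops to zero).
    """

    project_id: str
    impact_date: _dt.date
    result: ImpactResult
    expiry_by_entity: dict[EntityKey, _dt.date] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, expiry in self.expiry_by_entity.items():
            if expiry < self.impact_date:
                raise ModelInputError(
                    f"entry {self.project_id!r}: expiry for {key} precedes "
                    "the impact date"
                )


def _add_years(date: _dt.date, years: float) -> _dt.date:
    return date + _dt.timedelta(days=round(years * _DAYS_PER_YEAR))


def make_ledger_entry(
    project_id: str,
    impact_date: _dt.date,
    result: ImpactResult,
    bundle: ParameterBundle,
) -> LedgerEntry:
    """Attach per-entity expiry dates (impact date + that entity's recovery
    time) to an evaluated result."""
    expiry: dict[EntityKey, _dt.date] = {}
    for (level, entity), _ui in result.ultimate_by_entity().items():
        if level == "population":
            rt = bundle.species[entity].recovery_time_y
        elif level == "assemblage":
            rt = bundle.assemblage_vulnerability[entity].recovery_time_y
        else:
            rt = bundle.habitats[entity].recovery_time_y
        expiry[(level, entity)] = _add_years(impact_date, rt)
    return LedgerEntry(project_id, impact_date, result, expiry)


def cumulative_impacts(
    ledger: Iterable[LedgerEntry],
    candidate: ImpactResult | None,
    as_of: _dt.date,
) -> dict[EntityKey, float]:
    """Per-entity cumulative ultimate impacts as of a date.

    Sums the candidate's ultimate impacts with those of every ledger entry
    whose recovery is not yet complete (``as_of`` strictly before the
    entity's expiry).  Totals are per entity; assemblages are never summed
    together.
    """
    totals: dict[EntityKey, float] = {}
    for entry in ledger:
        for key, ui in entry.result.ultimate_by_entity().items():
            expiry = entry.expiry_by_entity.get(key)
            if expiry is not None and as_of >= expiry:
                continue
            totals[key] = totals.get(key, 0.0) + ui
    if candidate is not None:
        for key, ui in candidate.ultimate_by_entity().items():
            totals[key] = totals.get(key, 0.0) + ui
    return totals


# ---------------------------------------------------------------------------
# Threshold policy and recommendation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdPolicy:
    """Policy thresholds for the ultimate-impact comparison.

    cumulative_threshold
        Maximum acceptable cumulative ultimate impact for any single
        population, assemblage, or habitat (default 0.1).
    per_project_fraction
        No single project should consume more than this fraction of the
        cumulative threshold (default one fifth) without clear
        justification.
    approve_below / revise_below
        Per-project recommendation bands: below ``approve_below`` the
        project is recommended for approval; between the two bounds a
        revision is recommended; above ``revise_below`` the recommendation
        is rejection unless the exceedance is explicitly justified.
        ``approve_below`` defaults to cumulative_threshold x
        per_project_fraction.
    """

    cumulative_threshold: float = 0.1
    per_project_fraction: float = 0.2
    approve_below: float | None = None
    revise_below: float = 0.05

    def __post_init__(self) -> None:
        if self.cumulative_threshold <= 0:
            raise ModelInputError("cumulative threshold must be > 0")
        if not 0 < self.per_project_fraction <= 1:
            raise ModelInputError("per-project fraction must be in (0, 1]")
        if self.approve_below is None:
            # round the derived edge to 12 significant digits so that a UI
            # exactly at the nominal band boundary (e.g. 0.02) compares as
            # being on the boundary, not below it by one ulp
            edge = self.cumulative_threshold * self.per_project_fraction
            object.__setattr__(self, "approve_below", float(f"{edge:.12g}"))
        if not 0 < self.approve_below <= self.revise_below:
            raise ModelInputError(
                "recommendation bands must satisfy 0 < approve_below <= "
                f"revise_below (got {self.approve_below}, {self.revise_below})"
            )


_VERDICT_ORDER = {"approve": 0, "revise": 1, "reject": 2}


@dataclass
class EntityAssessment:
    candidate_ui: float
    cumulative_ui: float
    verdict: str
    rules: list[str] = field(default_factory=list)


@dataclass
class Recommendation:
    """Permit recommendation: the worst case over all impacted entities."""

    verdict: str
    per_entity: dict[EntityKey, EntityAssessment]
    triggered_rules: list[str]


def compare_to_thresholds(
    candidate: ImpactResult,
    cumulative_totals: Mapping[EntityKey, float],
    policy: ThresholdPolicy = ThresholdPolicy(),
    justified_override: bool = False,
) -> Recommendation:
    """Compare candidate and cumulative ultimate impacts to the policy.

    Per entity: candidate UI below ``approve_below`` -> approve; within
    [approve_below, revise_below] -> revise; above -> reject, downgraded to
    revise when the proposal carries an explicit justification for
    exceeding its share.  Independently, any cumulative total above the
    cumulative threshold forces rejection.  The overall verdict is the
    worst per-entity verdict.
    """
    per_entity: dict[EntityKey, EntityAssessment] = {}
    triggered: list[str] = []

    for key, ui in candidate.ultimate_by_entity().items():
        rules: list[str] = []
        if ui < policy.approve_below:
            verdict = "approve"
        elif ui <= policy.revise_below:
            verdict = "revise"
            rules.append(
                f"candidate UI {ui:.5g} within revision band "
                f"[{policy.approve_below:g}, {policy.revise_below:g}]"
            )
        else:
            if justified_override:
                verdict = "revise"
                rules.append(
                    f"candidate UI {ui:.5g} exceeds {policy.revise_below:g} "
                    "but an explicit justification was supplied"
                )
            else:
                verdict = "reject"
                rules.append(
                    f"candidate UI {ui:.5g} exceeds the per-project bound "
                    f"{policy.revise_below:g} without justification"
                )
        total = cumulative_totals.get(key, ui)
        if total > policy.cumulative_threshold:
            verdict = "reject"
            rules.append(
                f"cumulative UI {total:.5g} exceeds the threshold "
                f"{policy.cumulative_threshold:g}"
            )
        per_entity[key] = EntityAssessment(ui, total, verdict, rules)
        triggered.extend(f"{key[0]}:{key[1]}: {r}" for r in rules)

    if per_entity:
        verdict = max(
            (a.verdict for a in per_entity.values()), key=_VERDICT_ORDER.__getitem__
        )
    else:
        verdict = "approve"
    return Recommendation(verdict, per_entity, triggered)


# ---------------------------------------------------------------------------
# Appropriateness checklist
# ---------------------------------------------------------------------------

#: Recognized reasons a scientific or educational activity may be
#: appropriate inside a protected area.
APPROPRIATENESS_REASONS: dict[str, str] = {
    "facilitates_mpa_goals": (
        "research is consistent with and facilitates the MPA's goals"
    ),
    "evaluates_mpa_effectiveness": (
        "research evaluates MPA effectiveness and informs management"
    ),
    "studies_mpa_effects": (
        "research addresses ecological or socio-economic effects of MPAs"
    ),
    "requires_protected_population": (
        "research requires a protected population or ecosystem"
    ),
    "locally_rare_target": (
        "target species, assemblage or ecosystem is locally rare and not "
        "readily found outside local MPAs"
    ),
    "long_term_monitoring": (
        "continuation of a long-term monitoring program or research project"
    ),
    "unique_accessibility": (
        "protected area has unique accessibility, e.g. co-location with a "
        "research facility"
    ),
}


@dataclass
class AppropriatenessResult:
    passed: bool
    recognized: list[str]
    unrecognized: list[str]


def appropriateness_check(justifications: Iterable[str]) -> AppropriatenessResult:
    """Qualitative gate: the proposal passes iff it asserts at least one
    recognized appropriateness reason.  Never quantitative; all asserted
    reasons are attached to the report."""
    asserted = list(justifications)
    recognized = [j for j in asserted if j in APPROPRIATENESS_REASONS]
    unrecognized = [j for j in asserted if j not in APPROPRIATENESS_REASONS]
    return AppropriatenessResult(bool(recognized), recognized, unrecognized)
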