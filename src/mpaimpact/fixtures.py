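"""Synthetic benchmark scenarios: four worked case-study projects.

Four hypothetical projects in a kelp-forest / rocky-intertidal MPA
(modelled loosely on a central-California reserve, with wholly synthetic
abundances and areas):

1. ``purple_urchin`` -- collect and sacrifice 200 purple urchins with hand
   tools on shallow rock;
2. ``red_urchin`` -- the identical project on 10 of the much scarcer,
   slower-recovering red urchins;
3. ``lingcod`` -- tag-and-release 80 lingcod by hook and line;
4. ``intertidal_clearing`` -- clear fifty 1 m^2 rocky-intertidal plots of
   all organisms (no target declared, so no population-level output).

Published reference values exist for the population rows of cases 1-3
(proximate impacts of 0.216%, 0.118%, 0.265%; ultimate impacts 0.01298,
0.03889, 0.01061) and for the qualitative pattern of case 4 (sessile
invertebrates and macrophytes hit hardest, both in the revision band).
The species densities here are *back-solved* from those reference
proximate impacts -- the underlying field densities and areas are not
public -- so evaluating the generated inputs end-to-end reproduces the
reference population rows exactly, while the assemblage and habitat
parameters are synthetic values chosen to reproduce the qualitative
patterns only.  Reference values are never echoed by the evaluator; they
are stored solely so tests can compare against them.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

import yaml

from .core import HandlingSpec, HabitatParams, MethodProfile, VulnerabilityParams
from .decision import (
    ParameterBundle,
    PlotSchedule,
    ProjectComponent,
    SpeciesParams,
    TargetRef,
    ThresholdPolicy,
)
from . import io as _io

MPA_ID = "pt_lobos_synthetic"

SHALLOW_ROCK = "shallow reef and kelp forests"
ROCKY_INTERTIDAL = "rocky intertidal"

#: Areas (m^2) of the two habitats the cases touch.  The intertidal area is
#: chosen so fifty 1 m^2 plots are exactly 0.227% of the habitat.
SHALLOW_ROCK_AREA_M2 = 2.0e6
ROCKY_INTERTIDAL_AREA_M2 = 50.0 / 0.00227

CASE_IDS = ("purple_urchin", "red_urchin", "lingcod", "intertidal_clearing")


@dataclass(frozen=True)
class ReferenceRow:
    """Reference population-model outputs for one case (rounded values as
    tabulated in the published worked examples)."""

    pi_printed: float  # proximate impact, proportion (printed as percent)
    ui_printed: float  # ultimate impact, unitless
    rt_years: float
    interaction: float

    @property
    def pi_unrounded(self) -> float:
        """Back-solve the unrounded proximate impact from the (more
        precise) printed ultimate impact."""
        return self.ui_printed / ((self.rt_years / 2.0) * self.interaction)


#: Population rows of the three targeted reference cases.
REFERENCE_POPULATION_ROWS: dict[str, ReferenceRow] = {
    "purple_urchin": ReferenceRow(0.00216, 0.01298, rt_years=4.0, interaction=3.0),
    "red_urchin": ReferenceRow(0.00118, 0.03889, rt_years=22.0, interaction=3.0),
    "lingcod": ReferenceRow(0.00265, 0.01061, rt_years=8.0, interaction=1.0),
}

_N_TARGET = {"purple_urchin": 200.0, "red_urchin": 10.0, "lingcod": 80.0}

#: Handling specs per case (sacrifice for gonad analysis; tag-and-release;
#: clearing with release of mobile organisms).
_HANDLING = {
    "purple_urchin": HandlingSpec(mortality_target=1.0, mortality_nontarget=0.01,
                                  efficacy=1.0),
    "red_urchin": HandlingSpec(mortality_target=1.0, mortality_nontarget=0.01,
                               efficacy=1.0),
    "lingcod": HandlingSpec(mortality_target=0.12, mortality_nontarget=0.1,
                            efficacy=0.9),
    "intertidal_clearing": HandlingSpec(mortality_target=0.0,
                                        mortality_nontarget=0.02, efficacy=1.0),
}

_METHOD_FOR_CASE = {
    "purple_urchin": "hand_tools_collect",
    "red_urchin": "hand_tools_collect",
    "lingcod": "hook_and_line",
    "intertidal_clearing": "hand_tools_clearing",
}


def _methods() -> dict[str, MethodProfile]:
    return {
        "hand_tools_collect": MethodProfile(
            method_id="hand_tools_collect",
            mortality_by_group={
                "mobile_invertebrates": 0.05,
                "sessile_invertebrates": 0.10,
                "macrophytes": 0.10,
                "fishes": 0.0,
                "fishes_with_swim_bladder": 0.0,
            },
            susceptibility_by_assemblage={
                "fishes": 0.005,
                "mobile_invertebrates": 0.10,
                "sessile_invertebrates": 0.20,
                "macrophytes": 0.20,
            },
            habitat_alteration_by_class={
                SHALLOW_ROCK: 0.001,
                ROCKY_INTERTIDAL: 0.01,
            },
        ),
        "hook_and_line": MethodProfile(
            method_id="hook_and_line",
            mortality_by_group={
                "fishes": 0.10,
                "fishes_with_swim_bladder": 0.33,
                "mobile_invertebrates": 0.05,
                "sessile_invertebrates": 0.05,
                "macrophytes": 0.05,
            },
            susceptibility_by_assemblage={
                "fishes": 0.25,
                "mobile_invertebrates": 0.01,
                "sessile_invertebrates": 0.01,
                "macrophytes": 0.01,
            },
            habitat_alteration_by_class={SHALLOW_ROCK: 0.001},
        ),
        "hand_tools_clearing": MethodProfile(
            method_id="hand_tools_clearing",
            mortality_by_group={
                "sessile_invertebrates": 1.0,
                "macrophytes": 1.0,
                "mobile_invertebrates": 0.20,
                "fishes": 0.10,
            },
            susceptibility_by_assemblage={
                "sessile_invertebrates": 1.0,
                "macrophytes": 1.0,
                "mobile_invertebrates": 0.50,
                "fishes": 0.05,
            },
            habitat_alteration_by_class={ROCKY_INTERTIDAL: 0.01},
        ),
    }


def _species() -> dict[str, SpeciesParams]:
    """Species table with densities back-solved from the reference
    proximate impacts: density = lethal_factor * N / (PI * A_MPA)."""
    out: dict[str, SpeciesParams] = {}
    methods = _methods()
    meta = {
        "purple_urchin": ("mobile_invertebrates", None),
        "red_urchin": ("mobile_invertebrates", None),
        "lingcod": ("fishes", "fishes"),  # lingcod lack a swim bladder
    }
    for sid, row in REFERENCE_POPULATION_ROWS.items():
        assemblage, group = meta[sid]
        handling = _HANDLING[sid]
        m = methods[_METHOD_FOR_CASE[sid]].mortality_for(group or assemblage)
        lethal = (m + (1.0 - m) * handling.mortality_target) / handling.efficacy
        density = lethal * _N_TARGET[sid] / (row.pi_unrounded * SHALLOW_ROCK_AREA_M2)
        out[sid] = SpeciesParams(
            species_id=sid,
            assemblage=assemblage,
            habitat_class=SHALLOW_ROCK,
            density_per_m2=density,
            recovery_time_y=row.rt_years,
            interaction_index=row.interaction,
        )
    return out


def case_parameter_bundle() -> ParameterBundle:
    """The synthetic parameter bundle all four cases evaluate against."""
    return ParameterBundle(
        mpa_id=MPA_ID,
        methods=_methods(),
        species=_species(),
        assemblage_vulnerability={
            "fishes": VulnerabilityParams(8.0, 1.0),
            "mobile_invertebrates": VulnerabilityParams(9.0, 2.0),
            "sessile_invertebrates": VulnerabilityParams(6.0, 3.0),
            "macrophytes": VulnerabilityParams(8.0, 3.0),
        },
        habitats={
            SHALLOW_ROCK: HabitatParams(SHALLOW_ROCK, SHALLOW_ROCK_AREA_M2, 20.0),
            ROCKY_INTERTIDAL: HabitatParams(
                ROCKY_INTERTIDAL, ROCKY_INTERTIDAL_AREA_M2, 20.0
            ),
        },
    )


def case_components(case_id: str) -> list[ProjectComponent]:
    """The component list for one of the four benchmark cases."""
    if case_id not in CASE_IDS:
        raise ValueError(f"unknown case {case_id!r}; known: {CASE_IDS}")
    handling = _HANDLING[case_id]
    method = _METHOD_FOR_CASE[case_id]
    if case_id == "intertidal_clearing":
        return [
            ProjectComponent(
                method_id=method,
                habitat_class=ROCKY_INTERTIDAL,
                handling=handling,
                plots=PlotSchedule(plot_area_m2=1.0, n_plots=50, n_events=1,
                                   new_plots_each_event=False),
            )
        ]
    return [
        ProjectComponent(
            method_id=method,
            habitat_class=SHALLOW_ROCK,
            handling=handling,
            target=TargetRef(species_id=case_id, n_target=_N_TARGET[case_id]),
        )
    ]


_JUSTIFICATIONS = {
    "purple_urchin": ["requires_protected_population"],
    "red_urchin": ["requires_protected_population"],
    "lingcod": ["evaluates_mpa_effectiveness"],
    "intertidal_clearing": ["long_term_monitoring"],
}


def _proposal_document(case_id: str) -> dict:
    components = []
    for c in case_components(case_id):
        doc: dict = {
            "method_id": c.method_id,
            "habitat_class": c.habitat_class,
            "handling": {
                "mortality_target": c.handling.mortality_target,
                "mortality_nontarget": c.handling.mortality_nontarget,
                "efficacy": c.handling.efficacy,
            },
        }
        if c.target is not None:
            doc["target"] = {"species_id": c.target.species_id,
                             "n_target": c.target.n_target}
        if c.plots is not None:
            doc["plots"] = {
                "plot_area_m2": c.plots.plot_area_m2,
                "n_plots": c.plots.n_plots,
                "n_events": c.plots.n_events,
                "new_plots_each_event": c.plots.new_plots_each_event,
            }
        components.append(doc)
    return {
        "project_id": case_id,
        "mpa_id": MPA_ID,
        "impact_date": _dt.date(2026, 6, 1).isoformat(),
        "justifications": _JUSTIFICATIONS[case_id],
        "justified_override": False,
        "components": components,
    }


def generate_case_studies(out_dir: Path | str) -> dict[str, Path]:
    """Write a self-contained input set: the shared parameter tables plus
    one proposal file per case.  Returns the written paths keyed by name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = case_parameter_bundle()
    paths: dict[str, Path] = {}

    _io.write_methods(bundle.methods, out / "methods.csv")
    _io.write_species(bundle.species, out / "species.csv")
    _io.write_assemblages(bundle.assemblage_vulnerability, out / "assemblages.csv")
    _io.write_habitats(bundle.mpa_id, bundle.habitats, out / "habitats.csv")
    _io.write_policy(ThresholdPolicy(), out / "policy.json")
    for name in ("methods.csv", "species.csv", "assemblages.csv",
                 "habitats.csv", "policy.json"):
        paths[name] = out / name

    for case_id in CASE_IDS:
        p = out / f"proposal_{case_id}.yaml"
        with open(p, "w") as fh:
            yaml.safe_dump(_proposal_document(case_id), fh, sort_keys=False)
        paths[p.name] = p
    return paths
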