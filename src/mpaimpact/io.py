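"""File formats: parameter tables (CSV), policy (JSON), proposals
(YAML/JSON), the cumulative ledger (CSV), and the Table-style report.

All formats are plain text.  Schemas:

methods.csv
    method_id, group, mortality, assemblage, susceptibility,
    habitat_class, p_alt -- a long table where each row carries exactly one
    of the three (key, value) pairs: (group, mortality), (assemblage,
    susceptibility), or (habitat_class, p_alt).  ``mortality`` may be a
    numeric proportion or a categorical band label resolved through the
    mortality band table.
species.csv
    species_id, assemblage, habitat_class, density_per_m2, rt_years,
    interaction_index[, group]
assemblages.csv
    assemblage, rt_years, interaction_index
habitats.csv
    mpa_id, substrate, depth_band, position, area_m2, rt_years
abundance.csv
    year, event_id, value
ledger.csv
    project_id, impact_date, level, entity_id, pi, ui, expiry_date
policy.json
    cumulative_threshold, per_project_fraction, approve_below, revise_below
proposal.yaml / .json
    project_id, mpa_id, impact_date, justifications, justified_override,
    components (method_id, habitat_class, handling{...}, target{...} or
    plots{...})
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .core import (
    ASSEMBLAGES,
    HandlingSpec,
    HabitatParams,
    ImpactResult,
    MethodProfile,
    OrganismGroup,
    VulnerabilityParams,
)
from .decision import (
    LedgerEntry,
    ParameterBundle,
    PlotSchedule,
    ProjectComponent,
    Recommendation,
    SpeciesParams,
    TargetRef,
    ThresholdPolicy,
)
from .habitats import DepthBand, Position, Substrate, classify_habitat
from .params import (
    DEFAULT_MORTALITY_BANDS,
    AbundanceSample,
    MortalityBandTable,
)


class TableValidationError(ValueError):
    """A parameter table failed validation; the message lists file, row,
    and column."""


def _fail(path: Path | str, row: Any, column: str, message: str) -> None:
    raise TableValidationError(f"{path} (row {row}, column {column!r}): {message}")


def _check_range(path, row, column, value, lo=0.0, hi=1.0) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        _fail(path, row, column, f"not a number: {value!r}")
    if not (lo <= v <= hi):
        _fail(path, row, column, f"value {v} outside [{lo}, {hi}]")
    return v


def _is_blank(value: Any) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and not value.strip()
    )


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

def read_methods(
    path: Path | str, bands: MortalityBandTable = DEFAULT_MORTALITY_BANDS
) -> dict[str, MethodProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"method_id", "group", "mortality", "assemblage",
                "susceptibility", "habitat_class", "p_alt"}
    missing = required - set(df.columns)
    if missing:
        raise TableValidationError(f"{path}: missing columns {sorted(missing)}")

    mort: dict[str, dict] = {}
    susc: dict[str, dict] = {}
    palt: dict[str, dict] = {}
    for i, row in df.iterrows():
        mid = row["method_id"]
        if _is_blank(mid):
            _fail(path, i, "method_id", "missing method id")
        filled = [
            name
            for name, vcol in (("group", "mortality"),
                               ("assemblage", "susceptibility"),
                               ("habitat_class", "p_alt"))
            if not _is_blank(row[name]) or not _is_blank(row[vcol])
        ]
        if len(filled) != 1:
            _fail(path, i, "method_id",
                  "each row must fill exactly one of (group, mortality), "
                  "(assemblage, susceptibility), (habitat_class, p_alt)")
        kind = filled[0]
        if kind == "group":
            raw = row["mortality"]
            if isinstance(raw, str) and not raw.replace(".", "", 1).isdigit():
                try:
                    value = bands.lookup(raw.strip())
                except Exception as e:
                    _fail(path, i, "mortality", str(e))
            else:
                value = _check_range(path, i, "mortality", raw)
            try:
                group = OrganismGroup(str(row["group"]).strip())
            except ValueError:
                _fail(path, i, "group", f"unknown organism group {row['group']!r}")
            mort.setdefault(mid, {})[group] = value
        elif kind == "assemblage":
            a = str(row["assemblage"]).strip()
            if a not in ASSEMBLAGES:
                _fail(path, i, "assemblage", f"unknown assemblage {a!r}")
            susc.setdefault(mid, {})[a] = _check_range(
                path, i, "susceptibility", row["susceptibility"]
            )
        else:
            palt.setdefault(mid, {})[str(row["habitat_class"]).strip()] = _check_range(
                path, i, "p_alt", row["p_alt"]
            )

    methods: dict[str, MethodProfile] = {}
    for mid in sorted(set(mort) | set(susc) | set(palt)):
        missing_asm = set(ASSEMBLAGES) - set(susc.get(mid, {}))
        if missing_asm:
            raise TableValidationError(
                f"{path}: method {mid!r} is missing susceptibility for "
                f"assemblages {sorted(missing_asm)}"
            )
        methods[mid] = MethodProfile(
            method_id=mid,
            mortality_by_group=mort.get(mid, {}),
            susceptibility_by_assemblage=susc[mid],
            habitat_alteration_by_class=palt.get(mid, {}),
        )
    return methods


def write_methods(methods: Mapping[str, MethodProfile], path: Path | str) -> None:
    rows = []
    blank = {"group": "", "mortality": "", "assemblage": "",
             "susceptibility": "", "habitat_class": "", "p_alt": ""}
    for mid in sorted(methods):
        m = methods[mid]
        for g, v in m.mortality_by_group.items():
            rows.append({"method_id": mid, **blank, "group": g.value, "mortality": repr(v)})
        for a, v in m.susceptibility_by_assemblage.items():
            rows.append({"method_id": mid, **blank, "assemblage": a, "susceptibility": repr(v)})
        for h, v in m.habitat_alteration_by_class.items():
            rows.append({"method_id": mid, **blank, "habitat_class": h, "p_alt": repr(v)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_species(path: Path | str) -> dict[str, SpeciesParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"species_id", "assemblage", "habitat_class", "density_per_m2",
                "rt_years", "interaction_index"}
    missing = required - set(df.columns)
    if missing:
        raise TableValidationError(f"{path}: missing columns {sorted(missing)}")
    species: dict[str, SpeciesParams] = {}
    for i, row in df.iterrows():
        dens = float(row["density_per_m2"])
        if dens < 0:
            _fail(path, i, "density_per_m2", f"negative density {dens}")
        rt = float(row["rt_years"])
        if rt <= 0:
            _fail(path, i, "rt_years", f"recovery time must be > 0, got {rt}")
        idx = float(row["interaction_index"])
        if idx < 1:
            _fail(path, i, "interaction_index", f"index must be >= 1, got {idx}")
        group = None
        if "group" in df.columns and not _is_blank(row.get("group")):
            group = OrganismGroup(str(row["group"]).strip())
        sp = SpeciesParams(
            species_id=str(row["species_id"]),
            assemblage=str(row["assemblage"]).strip(),
            habitat_class=str(row["habitat_class"]).strip(),
            density_per_m2=dens,
            recovery_time_y=rt,
            interaction_index=idx,
            group=group,
        )
        species[sp.species_id] = sp
    return species


def write_species(species: Mapping[str, SpeciesParams], path: Path | str) -> None:
    rows = [
        {
            "species_id": sp.species_id,
            "assemblage": sp.assemblage,
            "habitat_class": sp.habitat_class,
            "density_per_m2": repr(sp.density_per_m2),
            "rt_years": repr(sp.recovery_time_y),
            "interaction_index": repr(sp.interaction_index),
            "group": sp.group.value,
        }
        for sp in species.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assemblages(path: Path | str) -> dict[str, VulnerabilityParams]:
    df = pd.read_csv(path, float_precision="round_trip")
    out: dict[str, VulnerabilityParams] = {}
    for i, row in df.iterrows():
        a = str(row["assemblage"]).strip()
        if a not in ASSEMBLAGES:
            _fail(path, i, "assemblage", f"unknown assemblage {a!r}")
        out[a] = VulnerabilityParams(
            float(row["rt_years"]), float(row["interaction_index"])
        )
    missing = set(ASSEMBLAGES) - set(out)
    if missing:
        raise TableValidationError(
            f"{path}: missing assemblage rows {sorted(missing)}"
        )
    return out


def write_assemblages(
    vuln: Mapping[str, VulnerabilityParams], path: Path | str
) -> None:
    pd.DataFrame(
        [
            {"assemblage": a, "rt_years": repr(v.recovery_time_y),
             "interaction_index": repr(v.interaction_index)}
            for a, v in vuln.items()
        ]
    ).to_csv(path, index=False)


def read_habitats(path: Path | str) -> tuple[str, dict[str, HabitatParams]]:
    df = pd.read_csv(path, float_precision="round_trip")
    habitats: dict[str, HabitatParams] = {}
    mpa_ids = set()
    for i, row in df.iterrows():
        mpa_ids.add(str(row["mpa_id"]))
        band = DepthBand(str(row["depth_band"]).strip())
        position = Position(str(row["position"]).strip())
        substrate = None
        if not _is_blank(row.get("substrate")):
            substrate = Substrate(str(row["substrate"]).strip())
        try:
            hclass = classify_habitat(
                substrate,
                depth_m=None if band is DepthBand.INTERTIDAL else
                {DepthBand.SHALLOW: 15.0, DepthBand.MID: 50.0,
                 DepthBand.DEEP: 150.0}[band],
                intertidal=band is DepthBand.INTERTIDAL,
                position=position,
            )
        except Exception as e:
            _fail(path, i, "depth_band", str(e))
        area = float(row["area_m2"])
        if area <= 0:
            _fail(path, i, "area_m2", f"area must be > 0, got {area}")
        habitats[hclass.name] = HabitatParams(
            habitat_class=hclass.name,
            area_mpa_m2=area,
            recovery_time_y=float(row["rt_years"]),
        )
    if len(mpa_ids) != 1:
        raise TableValidationError(
            f"{path}: expected exactly one mpa_id, found {sorted(mpa_ids)}"
        )
    return mpa_ids.pop(), habitats


def write_habitats(
    mpa_id: str, habitats: Mapping[str, HabitatParams], path: Path | str
) -> None:
    from .habitats import habitat_class_by_name

    rows = []
    for name, hp in habitats.items():
        hc = habitat_class_by_name(name)
        rows.append(
            {
                "mpa_id": mpa_id,
                "substrate": hc.substrate.value if hc.substrate else "",
                "depth_band": hc.depth_band.value,
                "position": hc.position.value,
                "area_m2": repr(hp.area_mpa_m2),
                "rt_years": repr(hp.recovery_time_y),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_abundance(path: Path | str) -> list[AbundanceSample]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        AbundanceSample(int(r["year"]), str(r["event_id"]), float(r["value"]))
        for _, r in df.iterrows()
    ]


def read_policy(path: Path | str) -> ThresholdPolicy:
    with open(path) as fh:
        raw = json.load(fh)
    return ThresholdPolicy(**raw)


def write_policy(policy: ThresholdPolicy, path: Path | str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "cumulative_threshold": policy.cumulative_threshold,
                "per_project_fraction": policy.per_project_fraction,
                "approve_below": policy.approve_below,
                "revise_below": policy.revise_below,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_parameter_tables(
    directory: Path | str,
) -> tuple[ParameterBundle, ThresholdPolicy]:
    """Load and validate a parameter bundle from a directory containing
    methods.csv, species.csv, assemblages.csv, habitats.csv and, if
    present, policy.json (defaults otherwise)."""
    d = Path(directory)
    methods = read_methods(d / "methods.csv")
    species = read_species(d / "species.csv")
    assemblages = read_assemblages(d / "assemblages.csv")
    mpa_id, habitats = read_habitats(d / "habitats.csv")
    policy_path = d / "policy.json"
    policy = read_policy(policy_path) if policy_path.exists() else ThresholdPolicy()
    bundle = ParameterBundle(
        mpa_id=mpa_id,
        methods=methods,
        species=species,
        assemblage_vulnerability=assemblages,
        habitats=habitats,
    )
    return bundle, policy


# ---------------------------------------------------------------------------
# Proposals
# ---------------------------------------------------------------------------

def load_proposal(path: Path | str) -> dict[str, Any]:
    """Load a proposal document (YAML or JSON) into a normalized dict with
    keys project_id, mpa_id, impact_date, justifications,
    justified_override, components (list of ProjectComponent)."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    components = []
    for spec in raw.get("components", []):
        handling = HandlingSpec(**spec.get("handling", {}))
        target = TargetRef(**spec["target"]) if "target" in spec else None
        plots = PlotSchedule(**spec["plots"]) if "plots" in spec else None
        components.append(
            ProjectComponent(
                method_id=spec["method_id"],
                habitat_class=spec["habitat_class"],
                handling=handling,
                target=target,
                plots=plots,
            )
        )
    date = raw.get("impact_date")
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    return {
        "project_id": raw["project_id"],
        "mpa_id": raw.get("mpa_id"),
        "impact_date": date,
        "justifications": raw.get("justifications", []),
        "justified_override": bool(raw.get("justified_override", False)),
        "components": components,
    }


# ---------------------------------------------------------------------------
# Ledger round-trip
# ---------------------------------------------------------------------------

def write_ledger(entries: list[LedgerEntry], path: Path | str) -> None:
    rows = []
    for e in entries:
        pis = {}
        if e.result.pi_population:
            pis.update({("population", k): v for k, v in e.result.pi_population.items()})
        pis.update({("assemblage", k): v for k, v in e.result.pi_by_assemblage.items()})
        pis.update({("habitat", k): v for k, v in e.result.pi_by_habitat.items()})
        for key, ui in e.result.ultimate_by_entity().items():
            rows.append(
                {
                    "project_id": e.project_id,
                    "impact_date": e.impact_date.isoformat(),
                    "level": key[0],
                    "entity_id": key[1],
                    "pi": repr(pis.get(key, 0.0)),
                    "ui": repr(ui),
                    "expiry_date": e.expiry_by_entity[key].isoformat(),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ledger(path: Path | str) -> list[LedgerEntry]:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return []
    entries: list[LedgerEntry] = []
    for pid, grp in df.groupby("project_id", sort=False):
        impact_date = _dt.date.fromisoformat(str(grp["impact_date"].iloc[0]))
        pi_pop: dict[str, float] = {}
        ui_pop: dict[str, float] = {}
        pi_asm: dict[str, float] = {}
        ui_asm: dict[str, float] = {}
        pi_hab: dict[str, float] = {}
        ui_hab: dict[str, float] = {}
        expiry: dict[tuple[str, str], _dt.date] = {}
        for _, row in grp.iterrows():
            level, entity = str(row["level"]), str(row["entity_id"])
            pi, ui = float(row["pi"]), float(row["ui"])
            if level == "population":
                pi_pop[entity], ui_pop[entity] = pi, ui
            elif level == "assemblage":
                pi_asm[entity], ui_asm[entity] = pi, ui
            elif level == "habitat":
                pi_hab[entity], ui_hab[entity] = pi, ui
            else:
                raise TableValidationError(f"{path}: unknown level {level!r}")
            expiry[(level, entity)] = _dt.date.fromisoformat(str(row["expiry_date"]))
        result = ImpactResult(
            pi_population=pi_pop or None,
            ui_population=ui_pop or None,
            pi_by_assemblage=pi_asm,
            ui_by_assemblage=ui_asm,
            pi_by_habitat=pi_hab,
            ui_by_habitat=ui_hab,
        )
        entries.append(LedgerEntry(str(pid), impact_date, result, expiry))
    return entries


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_REPORT_ASSEMBLAGE_ORDER = (
    "fishes", "mobile_invertebrates", "sessile_invertebrates", "macrophytes",
)


def render_report(
    results: Mapping[str, tuple[ImpactResult, Recommendation | None]],
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> pd.DataFrame:
    """Tabulate results, two rows per project: proximate impacts as
    percentages (3 decimals) and ultimate impacts as unitless numbers
    (5 decimals), with population, the four assemblages, the worst habitat,
    and the verdict."""
    rows = []
    for pid, (res, rec) in results.items():
        def _pop(d: dict[str, float] | None) -> float | None:
            if not d:
                return None
            return max(d.values())

        def _hab(d: dict[str, float]) -> float | None:
            return max(d.values()) if d else None

        pi_cells = {
            "population": _pop(res.pi_population),
            **{a: res.pi_by_assemblage.get(a) for a in _REPORT_ASSEMBLAGE_ORDER},
            "habitat": _hab(res.pi_by_habitat),
        }
        ui_cells = {
            "population": _pop(res.ui_population),
            **{a: res.ui_by_assemblage.get(a) for a in _REPORT_ASSEMBLAGE_ORDER},
            "habitat": _hab(res.ui_by_habitat),
        }
        verdict = rec.verdict if rec is not None else ""
        rows.append(
            {
                "project_id": pid,
                "impact_type": "proximate",
                **{
                    k: ("N/A" if v is None else f"{100 * v:.3f}%")
                    for k, v in pi_cells.items()
                },
                "verdict": verdict,
            }
        )
        rows.append(
            {
                "project_id": pid,
                "impact_type": "ultimate",
                **{
                    k: ("N/A" if v is None else f"{v:.5f}")
                    for k, v in ui_cells.items()
                },
                "verdict": verdict,
            }
        )
    columns = ["project_id", "impact_type", "population",
               *_REPORT_ASSEMBLAGE_ORDER, "habitat", "verdict"]
    return pd.DataFrame(rows, columns=columns)
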