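"""Coastal marine habitat classification and per-MPA habitat areas.

Habitats are classified by three features that strongly structure coastal
marine communities: substrate geomorphology (a binary rock/sediment split),
depth band (intertidal, 0-30 m, 30-100 m, >100 m), and position relative to
the seafloor (benthic vs. water column).  Pelagic habitat is treated as
distinct from the underlying benthic habitat only at depths greater than
30 m, which yields exactly ten named habitat categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class Substrate(str, Enum):
    ROCK = "rock"
    SEDIMENT = "sediment"


class Position(str, Enum):
    BENTHIC = "benthic"
    WATER_COLUMN = "water_column"


class DepthBand(str, Enum):
    INTERTIDAL = "intertidal"
    SHALLOW = "0-30m"
    MID = "30-100m"
    DEEP = ">100m"


class HabitatError(ValueError):
    """Invalid habitat specification or missing habitat."""


@dataclass(frozen=True)
class HabitatClass:
    """One of the ten named coastal habitat categories.

    ``substrate`` is ``None`` for the two pelagic classes: the water column
    is not differentiated by the substrate beneath it.
    """

    name: str
    substrate: Substrate | None
    depth_band: DepthBand
    position: Position


_BENTHIC_NAMES: dict[tuple[Substrate, DepthBand], str] = {
    (Substrate.ROCK, DepthBand.INTERTIDAL): "rocky intertidal",
    (Substrate.SEDIMENT, DepthBand.INTERTIDAL): "sandy beaches; marsh and mudflats",
    (Substrate.ROCK, DepthBand.SHALLOW): "shallow reef and kelp forests",
    (Substrate.SEDIMENT, DepthBand.SHALLOW): "estuaries; open coast soft-bottom",
    (Substrate.ROCK, DepthBand.MID): "mid-depth rocky reefs",
    (Substrate.SEDIMENT, DepthBand.MID): "mid-depth soft-bottom",
    (Substrate.ROCK, DepthBand.DEEP): "deep rocky reefs",
    (Substrate.SEDIMENT, DepthBand.DEEP): "deep soft-bottom",
}

_PELAGIC_NAMES: dict[DepthBand, str] = {
    DepthBand.MID: "shallow pelagic",
    DepthBand.DEEP: "deep pelagic",
}

HABITAT_CLASSES: tuple[HabitatClass, ...] = tuple(
    [
        HabitatClass(name, sub, band, Position.BENTHIC)
        for (sub, band), name in _BENTHIC_NAMES.items()
    ]
    + [
        HabitatClass(name, None, band, Position.WATER_COLUMN)
        for band, name in _PELAGIC_NAMES.items()
    ]
)

_BY_NAME: dict[str, HabitatClass] = {h.name: h for h in HABITAT_CLASSES}


def enumerate_classes() -> tuple[HabitatClass, ...]:
    """Return the ten habitat classes (8 benthic substrate x depth cells plus
    2 pelagic classes)."""
    return HABITAT_CLASSES


def habitat_class_by_name(name: str) -> HabitatClass:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise HabitatError(f"unknown habitat class {name!r}") from None


def depth_band_from_depth(depth_m: float) -> DepthBand:
    """Map a subtidal depth (m, positive down) to its depth band.

    Band boundaries are assigned to the shallower band (30 m -> 0-30 m,
    100 m -> 30-100 m): shallower habitats are typically the smaller ones,
    so the assignment is the conservative choice when areas differ.
    """
    if depth_m < 0:
        raise HabitatError(f"depth must be >= 0 m, got {depth_m}")
    if depth_m <= 30:
        return DepthBand.SHALLOW
    if depth_m <= 100:
        return DepthBand.MID
    return DepthBand.DEEP


def classify_habitat(
    substrate: Substrate | str | None,
    depth_m: float | None = None,
    *,
    intertidal: bool = False,
    position: Position | str = Position.BENTHIC,
) -> HabitatClass:
    """Classify a location into one of the ten habitat categories.

    Either ``intertidal=True`` or a subtidal ``depth_m`` must be given.
    ``substrate`` may be omitted (``None``) for water-column positions.

    Raises :class:`HabitatError` for the empty cells of the classification
    grid: the water column is not a distinct habitat in the intertidal or at
    depths of 30 m or less.
    """
    position = Position(position)
    if intertidal:
        band = DepthBand.INTERTIDAL
    else:
        if depth_m is None:
            raise HabitatError("either depth_m or intertidal=True is required")
        band = depth_band_from_depth(depth_m)

    if position is Position.WATER_COLUMN:
        if band not in _PELAGIC_NAMES:
            raise HabitatError(
                "water-column habitat is only distinct from benthic habitat "
                f"at depths greater than 30 m (got band {band.value!r})"
            )
        return _BY_NAME[_PELAGIC_NAMES[band]]

    if substrate is None:
        raise HabitatError("substrate is required for benthic habitat")
    return _BY_NAME[_BENTHIC_NAMES[(Substrate(substrate), band)]]


@dataclass
class MpaHabitatTable:
    """Habitat areas (A_MPA_hab, m^2) for one protected area.

    A class absent from ``areas`` means the MPA contains none of that
    habitat; asking for its area is an error rather than an implicit zero,
    because a proposal touching absent habitat is a data problem, not a
    zero-impact activity.
    """

    mpa_id: str
    areas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, area in self.areas.items():
            habitat_class_by_name(name)
            if area < 0:
                raise HabitatError(f"negative area for {name!r}: {area}")


def habitat_area_lookup(table: MpaHabitatTable, habitat: HabitatClass | str) -> float:
    """Area (m^2) of a habitat class within the MPA."""
    name = habitat.name if isinstance(habitat, HabitatClass) else habitat
    habitat_class_by_name(name)
    try:
        return table.areas[name]
    except KeyError:
        raise HabitatError(
            f"MPA {table.mpa_id!r} has no habitat of class {name!r}"
        ) from None
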