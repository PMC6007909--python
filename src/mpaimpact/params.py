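"""Precautionary parameterization helpers.

Most inputs to the impact equations cannot be measured directly for every
method-species combination, so the framework derives them conservatively:

* categorical expert mortality judgments are translated to numeric bands
  and the *high* end of the band is used;
* species interaction scores over seven interaction categories are summed
  and translated to a small integer interaction index (>= 1); an
  assemblage inherits the highest index of any member that may be
  susceptible, with unknown susceptibility conservatively treated as
  susceptible;
* assemblage recovery time is that of the slowest-recovering member;
* natural mortality can be estimated from longevity via a log-linear
  regression (Hoenig-type), from which a recovery time may be composed;
* species abundance is the lower quartile of a nonparametric bootstrap of
  annual mean density/cover, a deliberately pessimistic point estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import ModelInputError


class TemporalTrendWarning(UserWarning):
    """Annual means are strictly monotone; the bootstrap estimate ignores
    temporal trends and should be used with caution."""


# ---------------------------------------------------------------------------
# Categorical mortality bands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MortalityBandTable:
    """Ordered mapping from category label to a (low, high] proportion band.

    Lookup always returns the high endpoint of the band -- the conservative
    end of the expert judgment range.
    """

    bands: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        prev_high: float | None = None
        for label, (low, high) in self.bands.items():
            if not (0.0 <= low <= high <= 1.0):
                raise ModelInputError(
                    f"band {label!r} = ({low}, {high}] is not within [0, 1]"
                )
            if prev_high is not None and not math.isclose(low, prev_high):
                raise ModelInputError(
                    f"band {label!r} does not abut the previous band "
                    f"(starts at {low}, previous ends at {prev_high})"
                )
            prev_high = high
        if prev_high is None or not math.isclose(prev_high, 1.0):
            raise ModelInputError("bands must cover [0, 1]")

    def lookup(self, category: str) -> float:
        try:
            low, high = self.bands[category]
        except KeyError:
            raise ModelInputError(
                f"unknown mortality category {category!r}; "
                f"known: {sorted(self.bands)}"
            ) from None
        return high


#: Default bands.  The 33-66% "high" band anchors the scheme; the rest is
#: an overridable convention splitting [0, 1] into equal-width thirds plus
#: an explicit zero category for purely observational methods.
DEFAULT_MORTALITY_BANDS = MortalityBandTable(
    bands={
        "none": (0.0, 0.0),
        "low": (0.0, 0.33),
        "high": (0.33, 0.66),
        "very_high": (0.66, 1.0),
    }
)


def mortality_from_category(
    category: str, table: MortalityBandTable = DEFAULT_MORTALITY_BANDS
) -> float:
    """Numeric mortality for a categorical judgment: the high endpoint of
    the category's band."""
    return table.lookup(category)


# ---------------------------------------------------------------------------
# Interaction index
# ---------------------------------------------------------------------------

#: The seven interaction categories scored for potential strong interactors.
INTERACTION_CATEGORIES: tuple[str, ...] = (
    "keystone_predator",
    "structural_species",
    "ecosystem_engineer_autogenic",
    "ecosystem_engineer_allogenic",
    "facilitator",
    "dominant_competitor",
    "trophic_importance",
)

#: Default score-sum -> index translation: a species with no scored
#: interactions gets the neutral index 1; summed scores 1-3 map to 2 and
#: sums of 4 or more to 3.  Stored as (minimum sum, index) steps so
#: agencies can supply their own scale as data.
DEFAULT_SCORE_TRANSLATION: tuple[tuple[int, int], ...] = ((0, 1), (1, 2), (4, 3))


@dataclass(frozen=True)
class InteractionScoreSheet:
    """Qualitative interaction strengths (0 = none, 1 = moderate,
    2 = strong) for one species across the seven interaction categories."""

    species_id: str
    scores_by_category: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(INTERACTION_CATEGORIES) - set(self.scores_by_category)
        extra = set(self.scores_by_category) - set(INTERACTION_CATEGORIES)
        if missing or extra:
            raise ModelInputError(
                f"score sheet for {self.species_id!r} must cover exactly the "
                f"{len(INTERACTION_CATEGORIES)} interaction categories "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        for cat, s in self.scores_by_category.items():
            if s not in (0, 1, 2):
                raise ModelInputError(
                    f"score for {cat!r} must be 0, 1 or 2, got {s}"
                )

    @property
    def total(self) -> int:
        return sum(self.scores_by_category.values())


def interaction_index_from_scores(
    sheet: InteractionScoreSheet,
    translation: Sequence[tuple[int, int]] = DEFAULT_SCORE_TRANSLATION,
) -> float:
    """Translate summed interaction scores to an interaction index >= 1."""
    total = sheet.total
    index = 1
    for threshold, value in sorted(translation):
        if total >= threshold:
            index = value
    return float(max(index, 1))


def assemblage_interaction_index(
    members: Iterable[tuple[float, bool | None]],
) -> float:
    """Interaction index of an assemblage: the highest index of any member
    that may be susceptible to the study method.

    Each member is (interaction index, susceptible flag); ``None`` means
    susceptibility is unknown and is conservatively treated as susceptible.
    An assemblage with no susceptible strong interactor gets the neutral
    index 1.
    """
    members = list(members)
    if not members:
        raise ModelInputError("assemblage has no members")
    eligible = [idx for idx, susceptible in members if susceptible is not False]
    for idx, _ in members:
        if idx < 1:
            raise ModelInputError(f"interaction index must be >= 1, got {idx}")
    return max(eligible) if eligible else 1.0


# ---------------------------------------------------------------------------
# Recovery time
# ---------------------------------------------------------------------------

#: Combined-taxa log-linear regression coefficients for estimating natural
#: mortality from maximum age.  Overridable; taxon-specific fits may be
#: preferred when available.
HOENIG_A_DEFAULT = 1.46
HOENIG_B_DEFAULT = 1.01


def natural_mortality_hoenig(
    t_max: float, a: float = HOENIG_A_DEFAULT, b: float = HOENIG_B_DEFAULT
) -> float:
    """Instantaneous natural mortality rate (per year) from longevity:
    M = exp(a - b * ln(t_max)).  Strictly decreasing in t_max for b > 0."""
    if t_max <= 0:
        raise ModelInputError(f"maximum age must be > 0, got {t_max}")
    return math.exp(a - b * math.log(t_max))


def recovery_time_from_life_history(
    age_at_maturity_y: float, t_max: float, a: float = HOENIG_A_DEFAULT,
    b: float = HOENIG_B_DEFAULT,
) -> float:
    """Compose a recovery-time estimate as age at maturity + 1/M, i.e. the
    time to produce recruits plus the mean adult lifespan implied by the
    natural mortality rate.  A convenience, not an authority: recovery time
    remains a supplied parameter wherever better estimates exist.
    """
    if age_at_maturity_y < 0:
        raise ModelInputError("age at maturity must be >= 0")
    return age_at_maturity_y + 1.0 / natural_mortality_hoenig(t_max, a, b)


def assemblage_recovery_time(member_rts: Iterable[float]) -> float:
    """Recovery time of an assemblage: that of its slowest-recovering
    member."""
    rts = list(member_rts)
    if not rts:
        raise ModelInputError("assemblage has no members")
    if any(rt <= 0 for rt in rts):
        raise ModelInputError("recovery times must be > 0")
    return max(rts)


# ---------------------------------------------------------------------------
# Bootstrap abundance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbundanceSample:
    """One survey event's density (per m^2) or percent-cover value."""

    year: int
    event_id: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ModelInputError(f"abundance value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class BootstrapAbundance:
    """Lower-quartile bootstrap abundance estimate.

    ``all_zero`` flags the case where every survey value is zero: the
    species was either truly absent or undetectable, and the estimate
    cannot support an impact assessment -- an empirical pilot estimate is
    required instead.
    """

    value: float
    n_boot: int
    seed: int
    all_zero: bool = False


def _samples_by_year(samples: Sequence[AbundanceSample]) -> dict[int, np.ndarray]:
    by_year: dict[int, list[float]] = {}
    for s in samples:
        by_year.setdefault(s.year, []).append(s.value)
    # sort within year so the estimate is invariant to event ordering
    return {y: np.sort(np.asarray(v, dtype=float)) for y, v in by_year.items()}


def bootstrap_replicates(
    samples: Sequence[AbundanceSample], n_boot: int, seed: int
) -> np.ndarray:
    """Bootstrap replicate statistics of the grand mean of annual means.

    Scheme: for each replicate, resample the survey events *within each
    year* with replacement, take each year's mean, then average the annual
    means; years are visited in ascending order and one block of index
    draws is consumed per (replicate, year).  Deterministic for fixed seed.
    """
    if not samples:
        raise ModelInputError("at least one abundance sample is required")
    if n_boot < 1:
        raise ModelInputError(f"n_boot must be >= 1, got {n_boot}")
    by_year = _samples_by_year(samples)
    years = sorted(by_year)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot, dtype=float)
    for b in range(n_boot):
        annual = np.empty(len(years), dtype=float)
        for j, year in enumerate(years):
            vals = by_year[year]
            idx = rng.integers(0, len(vals), size=len(vals))
            annual[j] = vals[idx].mean()
        stats[b] = annual.mean()
    return stats


def bootstrap_abundance_estimate(
    samples: Sequence[AbundanceSample], n_boot: int = 1000, seed: int = 0
) -> BootstrapAbundance:
    """Conservative abundance estimate: the 25th percentile of the
    bootstrap replicate distribution of the grand mean of annual means.

    Warns with :class:`TemporalTrendWarning` when annual means are strictly
    monotone over three or more years, since the estimator assumes no
    trend.  All-zero inputs return 0 flagged ``all_zero``.
    """
    if not samples:
        raise ModelInputError("at least one abundance sample is required")
    if all(s.value == 0 for s in samples):
        return BootstrapAbundance(0.0, n_boot=n_boot, seed=seed, all_zero=True)

    by_year = _samples_by_year(samples)
    years = sorted(by_year)
    if len(years) >= 3:
        means = [float(by_year[y].mean()) for y in years]
        diffs = [b - a for a, b in zip(means, means[1:])]
        if all(d > 0 for d in diffs) or all(d < 0 for d in diffs):
            warnings.warn(
                "annual mean abundance is strictly monotone across "
                f"{len(years)} years; the bootstrap estimate does not "
                "account for temporal trends",
                TemporalTrendWarning,
                stacklevel=2,
            )

    stats = bootstrap_replicates(samples, n_boot=n_boot, seed=seed)
    value = float(np.percentile(stats, 25))
    return BootstrapAbundance(value, n_boot=n_boot, seed=seed)
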