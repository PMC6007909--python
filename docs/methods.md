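# Methods

## Model structure

A proposed project is decomposed into components, each a single
target/method/effort unit.  Every component is evaluated with up to three
models:

* **Population model** — only when the component declares a target
  species.  The proximate impact is the killed fraction of the MPA
  population: method mortality `M_meth`, plus handling mortality
  `M_hand` applied to the survivors, inflated by `1/Eff` for limited
  sampling efficacy, times the share of the population taken,
  `N / (Dens · A_MPA)`.
* **Assemblage model** — always, for each of the four assemblages
  (macrophytes, sessile invertebrates, mobile invertebrates, fishes).
  Assemblages are assumed uniformly distributed over their habitat, so the
  encountered fraction equals the sampled-area fraction
  `A_samp / A_MPA`; of that, the susceptible fraction `Suscep` suffers
  method mortality and survivors suffer non-target handling mortality.
* **Habitat model** — always, for each touched habitat class:
  `P_alt · A_samp / A_MPA`.

Ultimate impacts scale each proximate impact by `RT/2` (linear-recovery
assumption: the average shortfall over the recovery period is half the
initial impact) and, for biota, by the interaction index.  Habitat UI
carries no interaction index — all physical habitat is treated as vitally
important — and habitat recovery time is capped at 20 years at
construction; alterations likely to persist longer deserve case-by-case
scrutiny rather than a larger multiplier.

Impacts are summed within each entity (a species' population, one
assemblage, one habitat class) across components and across ledgered
projects, and never across assemblages: no single community-wide index is
computed anywhere in the package.

When an applicant is uncertain which of several method sets will be used,
each alternative is evaluated and the per-entity maximum governs the
assessment (the most impactful realistic combination).

## Units and conventions

* Areas in m²; recovery times in years; mortalities, susceptibilities,
  alteration probabilities, and efficacy as proportions in [0, 1].
* For cover-based taxa (e.g. algae, colonial invertebrates) the take `N`
  and density are both expressed in absolute cover-area units, which keeps
  `N / (Dens · A)` dimensionless exactly as for countable individuals.
* Proximate impacts are proportions: values above 1 (take exceeding the
  estimated population, or footprint exceeding the habitat) are clamped to
  1 with an `ImpactClampWarning` rather than rejected — the conservative,
  interpretable reading of an over-ambitious proposal.
* Ultimate impacts are unitless and unbounded above; no upper clamp is
  applied.
* `Eff = 0` is an input error, not an infinite impact: a method that never
  succeeds takes nothing, but the equation is undefined there, so such a
  procedure must be modelled differently (e.g. as incidental take only).
* There is no floor on recovery time: RT < 2 years legitimately yields
  UI < PI under the linear-recovery convention.
* The sampled-area inefficiency scalar defaults to 5 and is configurable;
  it magnifies the area occupied by the targeted organisms
  (`N / Dens`) to the area realistically worked to obtain them.
* Depth-band boundaries classify to the shallower band (30 m → 0–30 m,
  100 m → 30–100 m); shallower habitats are typically smaller, making this
  the conservative assignment.  The water column is a distinct habitat
  only below 30 m, giving exactly ten habitat classes (8 benthic, 2
  pelagic).  Shoreline linear features are converted to area upstream;
  this package consumes areas only.
* `fishes_with_swim_bladder` exists only for method-mortality lookup
  (barotrauma); for susceptibility and assemblage accounting it falls back
  to the fish assemblage.

## Precautionary parameterization

* **Categorical mortality** — expert judgments are banded; lookup returns
  the *high* endpoint.  Default bands: none = 0, low = (0, 0.33],
  high = (0.33, 0.66], very_high = (0.66, 1].  Only the 33–66% band is an
  anchored convention; the others are documented, overridable defaults
  supplied as data.
* **Interaction index** — seven interaction categories (keystone
  predation, structural/biogenic habitat, autogenic and allogenic
  engineering, facilitation, competitive dominance, trophic importance)
  scored 0–2, summed, and translated through a configurable step table
  (default: sum 0 → 1, 1–3 → 2, ≥4 → 3, chosen so the indices used in the
  benchmark cases — 1 and 3 — are reachable).  An assemblage inherits the
  maximum index over members that may be susceptible; unknown
  susceptibility counts as susceptible.
* **Recovery time** — an assemblage recovers as slowly as its
  slowest-recovering member.  A helper estimates natural mortality from
  longevity via `M = exp(a − b·ln(t_max))` (defaults a = 1.46, b = 1.01,
  a combined-taxa regression) and composes RT ≈ age at maturity + 1/M;
  this composition is a convenience and explicitly non-authoritative.
* **Abundance** — the lower quartile of a nonparametric bootstrap: survey
  events are resampled with replacement within each year, each replicate's
  statistic is the grand mean of annual means, and the 25th percentile of
  B = 1000 replicates (percentile method, linear interpolation) is the
  estimate.  Values are sorted within year before resampling so the result
  is invariant to event ordering, and the whole procedure is deterministic
  for a fixed seed.  No detrending is applied; strictly monotone annual
  means over ≥3 years raise a `TemporalTrendWarning`.  All-zero surveys
  return 0 with an `all_zero` flag — such cases need an empirical pilot
  estimate, not a model run.

## Decision rules

* Cumulative threshold 0.1 for the UI of any single population,
  assemblage, or habitat (comparable in spirit to potential-biological-
  removal mortality caps: it corresponds to extracting 10% of a
  short-lived neutral species or ~0.13% of a long-lived strong
  interactor).
* Per-project bands: UI < 0.02 (one fifth of the threshold) → approve;
  0.02–0.05 → revise; > 0.05 → reject unless the proposal carries an
  explicit justification flag, in which case the verdict is downgraded to
  revise and the override is logged.  The upper band extrapolates the
  two-band coding of the reference table; the justification semantics are
  left to the permitting agency.
* A cumulative total above the threshold forces rejection regardless of
  the override.  The overall verdict is the worst per-entity verdict.
* Ledger entries retain their full ultimate impact until the impacted
  entity's recovery time has elapsed (step expiry), then drop out; expiry
  is tracked per entity with that entity's own RT.  Step expiry is the
  conservative choice; linear amortization was considered and rejected as
  the default because it halves the protection of slow-recovering
  entities mid-recovery.  Known non-scientific extraction (e.g. quantified
  poaching) can be accounted for by pre-loading ledger entries.
* The appropriateness gate is a qualitative checklist of recognized
  reasons (MPA-goal facilitation, effectiveness evaluation, MPA-effects
  research, need for a protected population, locally rare target,
  long-term monitoring continuity, unique accessibility); at least one
  must be asserted before any quantitative evaluation is reported.

## Sensitivity analysis

One-at-a-time sweeps vary each input of a chosen impact equation across
its full range with the others fixed, standardize the input axis to
[0, 1], and rank parameters by maximum absolute finite-difference slope.
To keep outputs realistic the proximate models fix the targeted fraction
at 5% and the ultimate models fix the input PI at 1%; remaining constants
default to the medians of the shipped fixture tables (method mortality
0.33, handling mortality 0.1, efficacy 0.8, susceptibility 0.25,
alteration probability 0.33, RT 10 y, interaction 2).  Efficacy sweeps
start at ε = 0.01 to avoid the 1/Eff singularity; biota RT sweeps span
0–50 y, habitat RT 0–20 y, interaction 1–5.  The structural results —
susceptibility steepest for assemblage PI, recovery time dominant for all
UI models, method mortality dominant for population PI except below the
efficacy crossover — are properties of the equations and hold for any
reasonable constants; exact curve values depend on the constants and are
not a validation surface.

## Synthetic benchmark scenarios

Four benchmark projects (purple-urchin collection, red-urchin collection,
lingcod tagging, intertidal plot clearing) ship as a synthetic,
self-contained input set.  Reference values exist for the population rows
of the three targeted cases and for the qualitative pattern of the
clearing case, but the underlying field densities and habitat areas are
not public.  The fixture therefore back-solves each species' density from
the reference unrounded proximate impact
(`PI = UI / ((RT/2) · Interaction)`) so that end-to-end evaluation
reproduces the reference population rows, while method susceptibilities,
assemblage vulnerabilities, and habitat areas are synthetic values chosen
to reproduce the qualitative patterns (clearing hits sessile
invertebrates and macrophytes hardest, both in the revision band; hook
and line spreads impact through the fish assemblage).  Passing these
tests demonstrates the arithmetic and plumbing of the framework, not the
field accuracy of any parameter; a real deployment replaces every fixture
table with MPA-specific data.

## Problem sizes and numerical notes

The test suite's randomized equivalence checks use 1000 parameter draws
against literal-transcription oracles at 1e-12 absolute tolerance; the
bootstrap is cross-checked against an independent loop-and-fsum oracle at
B = 500–2000.  These sizes make the full suite run in seconds while
leaving no meaningful sampling slack.  The derived approve band edge
(threshold × fraction) is normalized to 12 significant digits so a UI
exactly at a nominal boundary (0.02) classifies as on the boundary.
Ledger expiry converts years to days with 365.2425 d/y.

## Known limitations

* Only lethal effects are modelled; sublethal stress and minor habitat
  disturbance enter, if at all, as small mortality/alteration
  probabilities.  Chemical and water-quality effects are out of scope.
* Footprints are areal, not spatially explicit; within-habitat patchiness
  of organisms and effort is ignored.
* The uniform-distribution assumption makes assemblage impacts
  proportional to area sampled, which is optimistic for aggregating
  species.
* Threshold values are policy inputs, not scientific outputs; the
  defaults are a conservative starting point, not a recommendation for
  any particular protected area.
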