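# Methods

## Model

A coastal zone in year *t* is represented as a point in a three-axis state
space (economic contribution, ecological services, human activity). Each
axis is spanned by a set of indicators; after range normalization and
weighting, the carrying capacity is the Euclidean modulus of the state
vector,

ECC(t) = √( Σ (wᵢ Eᵢ)² + Σ (wⱼ Rⱼ)² + Σ (wₖ Hₖ)² ),

computed per subsystem (restricting the sum) and overall. The overall
modulus always decomposes exactly into the three subsystem moduli
(ECC² = ECC_ec² + ECC_es² + ECC_ha², enforced to 1e-12). Because weights
sum to one within each subsystem and normalized values lie in [0, 1], each
subsystem modulus is at most 1 and the overall modulus at most √3.

The ideal state ECC\* is the modulus of a reference vector of normalized
values. Ideal values are taken on the **normalized** scale — the source
convention ("average value of the indicators") does not say raw or
normalized, but only the normalized reading makes ECC\* commensurable with
the yearly moduli it is compared against. Strategies: `mean` (default:
per-indicator mean over the study period), `max` (best observed), `fixed`
(user-supplied values in [0, 1]).

## Diagnosis chain

Yearly ECC is banded against multiples of ECC\* with left-open,
right-closed intervals:

| band | interval |
|---|---|
| light load | [0, 0.8·ECC\*] |
| loadable | (0.8, 1.0]·ECC\* |
| critical overload | (1.0, 1.2]·ECC\* |
| overload | (1.2, 1.4]·ECC\* |
| severe overload | (1.4·ECC\*, ∞) |

A value exactly on an edge belongs to the lower band (the "≤" reading of
the published thresholds). The band plus the year-on-year trend of ECC
determines the warning: light load/loadable are "no overload" (green, no
warning, trend ignored); critical overload maps to blue/light when slowing
and yellow/medium when aggravated; overload to orange/heavy and
red/extremely heavy. Severe overload has no separate warning row in the
published scheme; it is routed through the overload branch while keeping
its own carrying label, and — following the published table formatting —
is printed without a trend arrow in reports. Warning degree maps one-to-one
onto health level (no→very healthy, light→healthy, medium→sub-health,
heavy→unhealthy, extremely heavy→morbid). The chain is total and
deterministic over all (band, trend) pairs, and health severity is
non-improving in ECC for a fixed trend.

Two genuinely ambiguous cases are configurable with documented defaults:

- **Tie** (ECC equal to the previous year): the published rule prints both
  "≤" and "≥"; the default resolves ties as *slowing* (the lenient reading).
- **First year** (no predecessor): default *aggravated* (the conservative
  reading). The published study's first year is loadable/green, so its
  convention is unobservable; the choice only matters when a series starts
  beyond the loadable band.

## Preprocessing

- **Imputation.** Simple exponential smoothing per column over observed
  values in year order: s₁ = first observation,
  s_t = α·x_t + (1−α)·s_{t−1}. A missing cell is filled with the state
  carried from the most recent preceding observation; cells before the
  first observation are back-filled with it. α defaults to 0.5 (the source
  names the method but no coefficient); α = 1 is
  last-observation-carried-forward. A fully missing column is an error.
- **Normalization.** Column-wise min-max over the full study period,
  mirrored for negative-direction indicators (so 1 always means "loads the
  system most"). A constant column is set to 0.5 with a warning rather than
  erroring: the range transform is 0/0 there and the CV weighting gives the
  column weight zero, so any finite choice is inert.
- **Weighting.** Coefficient of variation V = σ/|x̄| with the population σ
  (divisor n, per the printed formula), computed on **raw** data by default
  (the published procedure says "original data"; a normalized basis is a
  config switch). Weights are normalized to sum to one **within each
  subsystem** — the published per-subsystem weight tables each sum to ≈1,
  which rules out global normalization. A zero-mean column under the raw
  basis is an error (CV undefined); an exactly constant column gets weight
  zero, detected by max = min rather than σ = 0 to avoid ulp-level float
  residue. Indicator direction is metadata the source never states; the
  shipped fixture marks pollutant discharges, beach-garbage density, the
  class-IV seawater share and population density as negative — an editorial
  reconstruction, clearly labelled.

## Contribution rates and shares

The published contribution-rate formula divides an "indicator carrying
capacity" by the subsystem modulus without defining the numerator. The
default here reads it **linearly**: an indicator's contribution is its load
w·Y averaged over years, divided by the sum of same-subsystem mean loads,
×100 — the simplest reading under which per-subsystem percentages sum to
100. A `squared` option (squared loads) is kept because the Euclidean
aggregation suggests it, but squared shares do not sum to the printed
subsystem-share values. Average subsystem shares likewise use the linear
denominator ECC_sub / (ECC_ec + ECC_es + ECC_ha) per year, averaged over
years: this reproduces the published 45/28/27% split, whereas squared
shares do not.

## Synthetic data

`generate_panel` draws per indicator a positive baseline (uniform around
100), a linear drift (uniform within ±5% of baseline per year) and Gaussian
noise (sd 5% of baseline), floored at 1% of baseline; missing cells are
placed uniformly at 2% by default, never in a column's first year. Defaults
mirror the motivating panel's shape (3 subsystems × 13 indicators ×
13 years, a 5-of-39 negative-direction minority, "a small number" of
missing values). It emulates the *statistical shape* the pipeline assumes —
positive, mildly trending, noisy annual series — not the marginal
distributions of any real coastal zone; a green test on synthetic data
establishes internal consistency of the pipeline, not empirical validity
of the indicator system.

`generate_scenario` inverts the chain for validation: given a target
carrying-band trajectory it emits a panel of already-normalized values
(one positive indicator per subsystem, weight one) whose yearly ECC sits at
the **midpoint** of each demanded band relative to a fixed ECC\* (default
0.5), together with the expected diagnosis records. Midpoints keep the
construction away from the boundary-inclusivity edges, where 3-decimal
printing is known to wobble. Infeasible requests (values outside [0, 1])
are rejected. The closed-loop property — pipeline output equals the
engineered records — holds exactly across a randomized suite of 100+
seeded trajectories.

## Numerical and reporting choices

- Classification always uses unrounded moduli; display rounding (3 decimals,
  half-up via `decimal`) happens only at the reporting boundary. The
  published tables show that band-edge years are sensitive to printed
  precision: re-classifying the *printed* series disagrees with the printed
  bands in exactly the years where the 3-decimal ratio crosses an edge the
  unrounded value evidently did not (overall 2011: 0.127/0.1048 = 1.2118;
  economic 2018: 0.071/0.0504 = 1.409; ecological 2007: 0.045/0.0461 =
  0.976). These are treated as printing artifacts, and agreement targets
  are ≥12/13 per series accordingly.
- Panel CSVs are written with `repr`-exact floats and parsed with Python's
  round-trip float parser, so write→parse is bit-exact including the
  missing mask.
- Panels require at least one year at construction; the diagnosis chain
  requires at least two (a trend needs a predecessor).

## Limitations

- The published indicator weights and contribution-rate percentages cannot
  be re-derived at desk scale: they require the undeposited yearbook panel.
  They are carried verbatim in the fixture and covered by integrity and
  property tests only.
- The warning scheme has no row for severe overload; the routing through
  the overload branch is a documented editorial decision.
- No uncertainty quantification on moduli, no forecasting, no alternative
  weighting schemes (entropy, AHP) beyond the CV method and a manual
  weight override.
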