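# Methods

## Analysis model

The package treats drought impact on vegetation productivity as three
measurable features of the joint distribution of a drought index and NPP:

* **Lag time** — the offset (0–60 months) maximizing the Pearson
  correlation between monthly de-seasonalized CWD (= P − PET) and NPP
  anomalies at one grid cell. The maximum itself is the moisture
  sensitivity. The maximum is taken over *signed* r: drought lowers both
  CWD and NPP, so the physically meaningful optimum is positive. Ties
  break toward the smallest lag. The overlap shrinks with the lag (no
  padding or wrap), matching the indexing convention "a one-month offset
  correlates NPP starting in month 2 with CWD starting in month 1".
* **Drought response** — the drought-year NPP anomaly, where the drought
  year is the *last* year of a run of years with standardized annual
  CWD ≤ −2. Merging consecutive extreme years into one event anchored at
  its end avoids double counting and gives each event a well-defined
  recovery window.
* **Legacy effects** — anomalies in post-drought years 1–4. Events with
  another extreme year inside that window are excluded: the later
  drought's response would contaminate the recovery estimate. Events
  whose window runs past the record end are kept with per-year
  availability flags; consumers may drop them.

Two baselines define "anomaly":

1. **Climate-normal baseline**: each cell's mean annual NPP over years
   with −1 ≤ Z ≤ 1, requiring at least 5 such years (a baseline from
   fewer is noise). Anomalies are absolute (gC m⁻² yr⁻¹) and integrate
   over the domain via exact spherical cell areas
   A = R²Δλ(sin φ₂ − sin φ₁), R = 6 371 000 m.
2. **Regression baseline**: per-cell OLS of annual NPP on annual CWD over
   the full record; anomalies are percent departures from the predicted
   value, 100·(NPP − N̂PP)/N̂PP. Only cells whose correlation is
   FDR-significant with r strictly > 0.3 are used — the same selection
   rule applied to the tree-ring chronologies that form the observational
   benchmark, which is what makes the two comparable. Non-positive
   predictions mask the cell-year (counted, warned).

Multiple events in a cell are averaged together but never across cells
before the spatial mean, preserving heterogeneity. Each model's spatial
mean trajectory feeds a percentile bootstrap (default n = 5000) over
models; the resulting CI measures **model-mean spread**, not sampling
uncertainty. The benchmark comparison reports, per post-drought year, the
observed/modeled depression ratio and the number of consecutive years
still depressed beyond a floor (default 1 percentage point).

Statistical conventions: sample standard deviation (ddof = 1) everywhere;
Benjamini–Hochberg FDR at α = 0.05 with one family per model map (the
family definition is a design choice; per-model maps are the unit a
practitioner inspects); p-values from the t-distribution with n − 2 df.
The p-value attached to a lag-optimized maximum ignores the selection over
61 lags and is therefore optimistic; it is reported nominally because the
lag search is treated as identification, not inference.

## Synthetic pseudo-model ensemble

The generator emulates only the statistical structure the analysis is
built to detect:

* **Climate** — precipitation with a sinusoidal seasonal cycle
  (70 ± 30 mm month⁻¹) modulated by lognormal yearly (σ = 0.2) and
  monthly (σ = 0.15) multiplicative variation; deterministic seasonal PET
  (60 ± 25 mm month⁻¹); seasonal temperature with white noise. Forced
  drought years are realized by per-cell bisection on a precipitation
  scale factor until the standardized annual CWD reaches Z ≤ −2.05, so
  downstream detection at −2 is never borderline. If zeroing the rain
  cannot reach the target the generator fails naming the year.
* **NPP** — NPP(t) = seasonal(t) + β·c(t − L) + AR(1) noise, floored at
  0, with c the de-seasonalized monthly CWD scaled by a per-cell scalar
  sd to unit variance, β the sensitivity (default 6 gC m⁻² month⁻¹ per
  z-unit), L the response lag (default 1 month). Defaults give a mean
  annual NPP of ~600 gC m⁻² yr⁻¹ and a 2:1 signal-to-noise ratio on the
  monthly anomaly (noise sd 3, AR(1) coefficient 0.3 — plausible
  ecological memory without swamping the signal).
* **Drought and legacy** — each extreme-drought year multiplies that
  year's NPP by (1 − 0.15); post-drought year k (from each event's last
  year) multiplies by (1 − legacy_profile[k−1]), default profile
  9/5/2/0%. Multiplicative application to total NPP matches the
  growth-fraction semantics of tree-ring benchmarks.
* **Forest map** — cells assigned round-robin to evergreen-needle /
  broadleaf-deciduous / mixed with configurable purity (default 0.8).

Two deliberate constructions make truth exactly recoverable:

* The lag is applied as a **circular shift** of c over the whole-year
  record. Per-calendar-month means of the shifted signal are then exactly
  zero, so with zero noise and zero legacy the de-seasonalized NPP is an
  exact scalar multiple of the shifted CWD anomaly and the lag search
  returns r_max = 1 (to float rounding) at exactly the injected lag. With
  a linear (truncated) shift the deseasonalization constants would differ
  by O(1/√years) per month and exactness would be lost.
* Standardizing c by a **single per-cell sd** (not per calendar month)
  keeps the annual sum of monthly anomalies exactly collinear with annual
  CWD, so the per-cell NPP~CWD regression is the data-generating model
  and null-legacy percent trajectories are unbiased.

AR(1) noise is an assumption — the noise structure of real TBM output is
not characterized — and is exposed in the config.

## Known estimator biases (visible in parameter recovery)

* **Regression absorption.** The NPP~CWD line is fitted on the full
  record, including drought and legacy years; the depressed years pull
  the fit down by roughly (total depression mass)/(record length) ≈ 1
  percentage point under default conditions, attenuating recovered legacy
  depressions toward zero by about that much. The drought-year depression
  is additionally absorbed into the slope (drought years sit at extreme
  CWD), so the recovered drought-year departure (≈ −11.6%) understates
  the injected −15%. The analysis convention accepts both: expected NPP
  "already accounts" for water limitation.
* **Lag carryover.** With a response lag of L months, the last L months
  of the drought year's climate anomaly spill into the next calendar
  year's NPP. A 1-month lag adds ≈ 1.2 percentage points of genuine
  year-1 depression that is response, not legacy. The statistical null
  (zero injected legacy) therefore uses L = 0.
* **Exclusion selection.** Surviving events' post-drought years are
  conditioned on containing no further extreme drought, hence slightly
  wet-biased: late post-drought years sit a few gC m⁻² *above* the
  climate-normal mean while the CWD-referenced percent anomaly is ~0.
  This is why absolute and percent trajectories are only guaranteed to
  agree in sign where the injected signal dominates (drought year and
  year 1).

## Numerical choices

* Cells whose annual series is constant to float rounding are masked as
  degenerate in Z-scoring (sd ≤ 1e−12 × max(|mean|, 1)), with the count
  reported.
* A cell-year with any masked month is masked in annual totals
  (conservative).
* Nearest-neighbour regridding uses exact great-circle nearest centers
  (KD-tree on unit-sphere coordinates); target cells farther than 1.5
  source-cell diagonals from any source center are masked and counted.
* The spatial domain is the contiguous US (25–50°N, 125–60°W) and Europe
  (36–70°N, 10°W–36°E), inclusive on cell centers. Exclusion is forward
  only: a *prior* event within 4 years does not void an event.
* Bootstrap is the plain percentile method; percentile bands use numpy's
  linear interpolation convention.
* Dominant-driver attribution lag-optimizes both P and T over the same
  0–60 month window and picks the larger |r_max| among FDR-significant
  drivers; if only one is significant it wins, if neither the cell is
  masked.

## Problem sizes and what passing tests show

Tests and the acceptance script run on grids of 9–500 cells, 61-year
monthly records, and up to 12 pseudo-models — sizes at which every
statistic is estimated from hundreds to thousands of events and the suite
completes in seconds. The generator reproduces the *structure* real
gridded TBM output would have (seasonality, lagged linear moisture
response, multiplicative legacy, autocorrelated noise) but none of its
physics: no radiation, nitrogen or CO₂ effects, no mortality, no spatial
correlation of noise across cells, and forest types carry no distinct
response parameters. Passing parameter-recovery tests therefore
demonstrates that the estimators are correct and calibrated, not that any
particular real model ensemble behaves this way; headline magnitudes from
the original multi-model archives (e.g. domain-integrated PgC losses) are
reproduced only as arithmetic consistency checks, not re-derived from
real data.
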