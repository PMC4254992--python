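# Methods

## The population model

`krillsim` simulates an Antarctic krill (*Euphausia superba*) population as
a set of individuals, each carrying a body length (mm) and an age (months),
tracked at monthly resolution for ten years. The model is deliberately
simple — no density dependence, no spatial structure, no stock–recruit
feedback — because its purpose is not realism per se but a controlled
setting in which *absolute recruitment is known*, so that length-based
recruitment indices can be validated against truth.

Each month, every individual passes through three processes in a fixed
order, followed by any recruit release:

1. **Mortality.** Survival is Bernoulli with probability `1 − M/100`,
   where `M` is a proportional monthly rate (%). `M` relates to the
   exponential decay rate `m` (yr⁻¹) of aggregate models through
   `M = 100·(1 − e^(−m/12))`; the default `M = 8.0 %/month` is the
   conventional rounding of `m = 1.0 yr⁻¹` (exact value 7.9945…%). The
   exact conversion is exposed as `monthly_mortality_percent`. Survivors
   age by one month. There is no maximum age; longevity (4–7 yr in the
   wild) emerges from mortality alone.

2. **Growth.** A seasonally modulated von Bertalanffy increment:
   `L ← L + (L∞ − L)(1 − e^(−k_t))` with monthly coefficient
   `k_t = (K/12)(1 + SV(t))`. `SV(t)` is an amplitude-scaled cosine with
   a 12-month period, peaking in February (the austral SST maximum) and
   reaching its trough in August; at full amplitude (the default) growth
   stops entirely in mid-winter. Because the cosine sums to zero over any
   12 consecutive months, the `k_t` sum to exactly `K` per year:
   length-at-age at annual boundaries sits on the plain aseasonal von
   Bertalanffy curve regardless of amplitude. This normalisation is a
   design choice — the published seasonal sub-model it emulates is only
   sketched in our sources — and is the property the growth tests pin
   down. Defaults `L∞ = 60 mm`, `K = 0.45 yr⁻¹` are a curve commonly used
   for krill; they reproduce the recruit initial mean length exactly as
   length-at-age-1: `60·(1 − e^(−0.45)) = 21.742 mm`.

3. **Capture sampling.** Each individual is independently "available for
   capture" with probability given by a logistic selectivity ogive
   `P(L) = 1/(1 + e^(−2 ln3 (L − L50)/SR))` (`SR = L75 − L25`).
   Availability is re-drawn every month; available individuals are
   measured but never removed, and no further sub-sampling is applied.
   **The default ogive (L50 = 35.5 mm, SR = 7.0 mm) is an approximation**
   of the published selectivity of a commercial krill trawl with a
   15.4 mm diamond-mesh codend: L50 near the reported ~50% retention
   length, SR narrow enough that the 5% availability length (≈26 mm) lies
   above the recruit release length (21.7 mm), so a fresh cohort takes a
   few months of growth to appear in catches. Users with a gear-specific
   fitted ogive should substitute their own parameters; the fitted
   power-law coefficients are sensitive to this choice.

**Recruitment.** An annual event releases one-year-olds (age 12 months)
over the summer: 25% in November, 50% in December, 25% in January. The
event attributed to calendar year *y* comprises the Nov/Dec releases of
year *y−1* plus the Jan release of year *y*, drawn as a single number

    R_y = round(R_mean · (1 + R_R/100)),   R_R ~ Uniform(−Rvar, +Rvar)

with `Rvar` the recruitment-variability amplitude (%). Initial lengths are
Normal(21.742, 2) mm, truncated to (0, L∞) (with sd 2 mm the truncation is
essentially never triggered; it exists to protect growth monotonicity).
Initial length is sampled once at release, not re-centred per release
month. Releases happen *after* the month's capture sampling, so a pulse is
first seen in catches the following month. The simulation starts empty;
`n_years + 1` events are drawn so the final calendar year still receives
its November/December pulse from the following event. Ten years are ample
for demographic steady state (verified by a same-calendar-month population
comparison between years 9 and 10 under constant recruitment).

## Indices

From each monthly catch sample two order statistics are computed: the
median length (mm; midpoint convention for even n) and **F40**, the
percentage of individuals with length *strictly* below 40 mm (lengths are
continuous, so the strictness convention has measure zero). Each is
summarised per calendar year by its minimum, maximum and span, giving six
candidate annual recruitment indices. A month with an empty catch (only
possible during burn-in or under extreme parameters) is recorded as
missing and excluded from the annual summary.

## Index selection

Two criteria guide index choice: monotone relation to absolute recruitment
and stability of that relation across Rvar levels. `krillsim.selection`
formalises an otherwise visual assessment as three scores (Spearman rank
correlation of recruitment-decile bin means; normalised within-bin
dispersion; coefficient of variation of per-Rvar power-law coefficients)
and ranks lexicographically by monotone *strength* (|ρ|, so a cleanly
decreasing index like the median minimum counts as monotone), then spread,
then stability, with alphabetical tie-break. Only the resulting ordering
is meaningful — the score magnitudes are artifacts of the formalisation.
On pooled campaigns the annual-minimum F40 (`f40_min`) ranks first, which
is the selection the downstream regression assumes.

## Regression layer

With `I` = annual-minimum F40 (%) and `R` = recruits in the same year, the
index-to-recruitment relation is a power law, fitted by OLS on logs:

    ln R = β₀ + β₁ ln I + ε,  ε ~ N(0, σ²)

Fits go through `statsmodels.OLS`; tests verify them against hand-computed
normal equations. Prediction intervals use the exact pointwise OLS formula
on the log scale, `t_{α/2,n−2}·s·sqrt(1 + 1/n + (x − x̄)²/Sxx)`,
exponentiated (a constant-width log-scale band is available behind
`method="band"`). Because the bounds are curves in log-log space, the fit
also reports `(intercept, slope)` pairs of straight lines least-squares
fitted through each bound over the observed index range — the
parameterisation conventionally tabulated alongside the mean fit. Reported
parameter variances are OLS coefficient sampling variances.

Performance metrics:

* **Coverage probability** — percentage of simulated recruitment values
  inside the 95% prediction intervals (in-sample).
* **Prediction error** — signed, `100·(predicted − simulated)/simulated`
  (%); overestimates positive. The signed form reproduces the
  characteristic asymmetry at high Rvar: simulated recruitment is bounded
  above by `R_mean·(1 + Rvar/100)` while the regression extrapolates
  freely upward.
* **Multiannual fit** — OLS of final-year `ln R` on `k` consecutive
  annual-minimum-F40 values (current year first, up to k = 6); `k = 1`
  coincides numerically with the power-law fit. Cohorts persist in the
  length structure for several years, so lagged index values carry
  information about the current year's recruitment.
* **Mean bias reduction** — the *relative* reduction in mean absolute
  prediction error, `100·(mean|e₁| − mean|e_k|)/mean|e₁|` (%). The raw
  percentage-point difference is available via `relative=False`; the
  relative form is the scale on which multiannual improvement is
  conventionally reported, and the only one consistent with the observed
  error magnitudes (at Rvar = 30% the mean absolute error of the
  single-year fit is ~7–10%, so double-digit point reductions are
  structurally impossible while double-digit relative reductions occur).

## Scale invariance and problem sizes

The full-scale study design (R_mean = 4×10⁶, 2,000 simulations × 10 Rvar
levels) implies steady-state populations of millions of individuals.
All quantitative checks here exploit an exact invariance instead: indices
are proportions/order statistics, so rescaling `R_mean` by `c` leaves
their distributions unchanged up to sampling noise; `β₁`, coverage and
percentage errors are invariant, while `β₀` shifts by exactly `ln c`
(verified as a property test, and distributionally by a Kolmogorov–Smirnov
comparison between scales). Desk-scale campaigns therefore use
`R_mean = 4×10⁴` (c = 0.01, corrected as `β₀ + ln 100`): the acceptance
script runs 500 replicates at Rvar = 100% and 50% (binomial s.e. of a
coverage estimate ≈ 1%) and 300 at Rvar = 60% and 30%; test fixtures use
400/400/250/250/250 at Rvar = 100/50/60/30/90%. One ten-year simulation at
this scale takes ~0.25 s, a full acceptance run a few minutes.

## Numerical and degenerate-input choices

* One root seed per campaign; independent child streams per simulation
  via `numpy` seed sequences — campaigns are exactly reproducible and
  replicates independent.
* Recruit counts are rounded to the nearest integer per release month
  (bias negligible at desk scale and above).
* Log-log fits require strictly positive inputs; campaign rows with
  non-positive recruits or index values are dropped before fitting (at
  Rvar = 100% a zero draw has probability ~10⁻⁵ at desk scale; F40-min is
  in practice never 0 under defaults). Degenerate designs (constant
  index, collinear lags) raise errors rather than returning garbage.
* An empty monthly catch yields a missing month, excluded from annual
  summaries; a year with all months missing is an error.

## What the simulator does and does not emulate

The generator reproduces: pulsed summer recruitment with controlled
interannual variability, co-existing cohorts with seasonal growth and
constant mortality, and gear-selective observation of the length
structure. It does *not* emulate: interannual variation in growth,
mortality, or recruitment timing; spatial or effort heterogeneity in
sampling; observation error beyond gear selectivity; any feedback from
the adult stock to recruitment; or fishing removals (capture is purely
observational). Passing tests therefore demonstrate that the index
methodology behaves as described *under these idealised conditions* — not
that a particular ogive or growth curve is correct for any real fishery,
and conclusions transfer only to gears with selectivity similar to the
parameterised ogive.

## Known limitations

* The seasonal-growth normalisation is one consistent reading of a
  sub-model whose exact published equations were not available; other
  phasings/normalisations would shift monthly index traces (not annual
  length-at-age).
* The default selectivity ogive is an approximation (see above); fitted
  β₀/β₁ values shift with `(L50, SR)`.
* Prediction-interval coverage is evaluated in-sample, matching the
  original evaluation design; out-of-sample coverage would be slightly
  lower.
* At very small `R_mean` (≲10³) integer rounding and small-sample noise
  in monthly order statistics become visible; desk scale (4×10⁴) is the
  smallest size used for quantitative comparisons.
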