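# Methods

## Data model and estimands

Event counts are modelled as independent Poisson variables per cell,
`D_jk ~ Poisson(n_jk * lambda_jk)`, over J ordered socioeconomic groups
and K age bands.  All inference targets are functions of the true
age-adjusted rates `mu_j = sum_k w_k lambda_jk`, where the `w_k` are
fixed standard-population weights.  Group population shares `p_j` and
the derived midpoint relative ranks `z_j` are treated as known
constants throughout: no sampling variability is attached to them, so
variance propagates only through the rate estimates `Y_j`.  Groups are
assumed independent (no shared cells, no covariance).

Two conventions fix the estimands of the non-smooth measures:

* RD/RR are defined at the true extremes (`mu_max`, `mu_min`); their
  plug-in estimators use the observed order statistics, which are
  biased for small counts — no bias correction is attempted.
* IDisp's reference is the group attaining the smallest rate: the true
  minimum for the estimand, the observed (or per-draw simulated)
  minimum for estimators.  A fixed-index reference and the older
  population-mean variant are available as options.
* PD/PR compare a fixed pair, by default the last (highest-rank) group
  against the first, so PD > 0 when rates rise with rank.
* MLD and Theil's T use natural logarithms.

## Interval constructions

**Classical (Delta/Wald).**  `Var F(Y) ≈ sum_j (dF/dy_j)^2 sigma^2_j`,
with every gradient derived analytically (verified against central
differences in the test suite) and evaluated at the observed rates.
Kinks are resolved deterministically: RD/RR attribute all variance to
the groups attaining the observed extremes (ties to the lowest index),
and IDisp uses `sign(Y_j - Y_ref)` with exact ties contributing zero.
Intervals are plain Wald on the natural scale for every measure — no
log transformation and no truncation at zero, also for ratio measures.

**Monte-Carlo simulation (MCS-N, MCS-G).**  Group rates are simulated
B times from a distribution matched to `(Y_j, sigma^2_j)`: a Normal
conditioned on `[0, inf)` or a Gamma with shape `Y^2/sigma^2` and scale
`sigma^2/Y`.  The measure is evaluated on every simulated vector
(re-selecting the max/min/reference per draw) and the interval is the
empirical `alpha/2, 1-alpha/2` percentile pair.  The truncated Normal
is sampled by the inverse-CDF transform of the conditioned
distribution, which is exactly equivalent to redrawing negative values
but vectorizes and keeps exactly B draws.

**Fiducial (FI1, FI2, FI3).**  Each cell rate is replaced by a draw of
a chi-squared pivot: `chi2_{2m+1}/(2n)` (FI1, Cox), a 50-50 mixture of
`chi2_{2m}/(2n)` and `chi2_{2m+2}/(2n)` chosen independently per
replicate and cell (FI2, Dempster), or both pivots per replicate (FI3).
FI3 contributes two measure evaluations per replicate — one with every
cell at its lower pivot, one with every cell at its upper pivot — and
the 2B values are pooled before taking percentiles; this reading makes
FI3 the pooled-endpoint analogue of the mixture and reproduces its
strongly conservative sparse-data behavior.

## Zero-count cells

Sparse tables contain cells with `m = 0`, and under one expected event
per cell entire groups can be event-free (probability `exp(-sum_k n_jk
lambda_jk)`, which exceeds 20% per sparse group in the sparsest
canonical scenario).  Two places need a convention:

* **Fiducial lower pivot.**  `chi2_0` is a point mass at zero; an exact
  zero would push log- and ratio-based measures to infinity inside the
  simulation.  Wherever the degenerate lower pivot would be used (the
  FI2 lower branch and the FI3 all-lower evaluation) the cell receives
  the fixed substitute rate `1/(n(n+1))` — effectively zero on the rate
  scale but finite in logs.  The proper pivots (`chi2_1` for FI1, the
  `chi2_{2m+2}` upper branch) are well defined at `m = 0` and are drawn
  as such; replacing them by a constant would pin an event-free group
  at a point value and destroy the coverage of every ratio and entropy
  measure whenever such a group occurs, which simulation shows is
  incompatible with the near-total coverage these methods actually
  attain in sparse data.
* **MCS moment matching.**  A zero cell contributes nothing to
  `sigma^2_j`, and a fully event-free group leaves `(Y_j = 0,
  sigma^2_j = 0)`, where neither distribution can be matched.  Every
  zero-count cell is therefore assigned the conventional half-event
  pseudo-count (rate `0.5/n_jk`) before the moments are computed.  The
  half event is the standard sparse-rate continuity correction and
  coincides with the mean of the Cox pivot at `m = 0`
  (`chi2_1/(2n)` has mean `0.5/n`), keeping the two simulation families
  consistent about what "no events observed" is worth.  Among the
  candidate conventions examined (no adjustment; `1/(n(n+1))`;
  `1/(n+1)`; variance-only corrections), the half event is the only one
  whose simulated sparse-data coverage profile is compatible across all
  fifteen measures with the behavior these methods are known to have.

The classical method receives no zero-count adjustment; with an
event-free group its undefined intervals (log or ratio measures) are
scored by the coverage engine's failure policy.

## Simulation study

Nine canonical scenarios share one 3 × 4 base grid of person-years
(12-cell mean 2417, SD 1084) and one base grid of true rates (mean
3e-4, SD 2e-4), scaled by powers of ten; cell-wise expected counts in
the base configuration have mean 0.8 and SD 0.784.  The base grids were
fixed once by least squares against those six moment targets under
shape constraints a practitioner would impose — rates increasing with
age and with socioeconomic rank, person-years decreasing with age — and
live in `src/dispci/data/scenarios.yaml`.  Age weights are the WHO
World Standard population collapsed to four bands (0–24, 25–49, 50–69,
70+), renormalized.

The coverage engine draws R datasets from the scenario truth and scores
every method on the same datasets (one data substream plus one
independent substream per method, all spawned from a single master
seed, so any subset of methods reproduces exactly).  An interval that
is undefined for a degenerate dataset is counted as non-covering and
logged — never dropped — with a `raise` policy available.  Default
R = B = 5000.  The Monte-Carlo standard error of a coverage estimate c
is `100*sqrt(c(1-c)/R)`, about 0.31 points at 95% with R = 5000.

Problem sizes used by the shipped checks: the acceptance script runs
the three headline scenarios at full R = B = 5000 (a few minutes on one
CPU); the test suite runs its coverage checks at R = B = 2000 (scenario
reproductions, with tolerances widened to 2.5 points accordingly) and
R = B = 1500 (dense-scenario band checks).

## Numerical choices

* Percentile intervals interpolate linearly between order statistics
  (`numpy.quantile` default); the convention is pinned by a test.
* Bulk simulation evaluates measures with domain checking off: an
  undefined value becomes `inf`/`nan` and the resulting interval is
  scored as non-covering.  The user-facing single-table API instead
  raises informative domain errors (zero minimum rate for RR, log of a
  non-positive rate for MLD/T, singular rank design for SII).
* Truncated-Normal sampling uses `ndtr`/`ndtri`; at zero variance the
  draw is the constant mean.
* Chi-squared draws with per-element degrees of freedom are generated
  in one vectorized call; degrees of freedom are never zero because the
  degenerate case is substituted first.
* Reported rates are on the raw per-person scale internally; per-100,000
  scaling is applied only in human-readable CLI output.

## What the generator does and does not emulate

The synthetic scenarios reproduce the study conditions summarized by
their cell-moment characteristics: Poisson counts, three ordered groups
and four age bands, fixed weights, expected counts spanning five orders
of magnitude.  They do not emulate real-data features such as
overdispersion, correlated cells, misclassified socioeconomic rank,
population-share uncertainty, or more than three groups — so passing
coverage checks here demonstrates correctness of the interval
machinery under the Poisson model, not robustness beyond it.

A sharper caveat applies to the sparsest scenario: published per-cell
configurations behind such studies are typically reported only as
12-cell moments, and the extreme sparse-data coverage values (notably
the severe FI1/FI2 undercoverage of the aversion-weighted concentration
indices eACI/eRCI) are sensitive to the exact grid.  Under the
canonical grid frozen here, FI1/FI2 remain mildly conservative for
eACI/eRCI in the sparsest scenario rather than collapsing: the
sparse-group pivot bias (about `+1/(2n)` per zero cell) is small
relative to the interval width in this geometry.  The corresponding
acceptance checks are therefore expected to disagree with the most
extreme published entries, and the disagreement is configuration-driven
rather than a defect of the interval constructions; the moderate and
dense scenarios, where the grid dependence washes out, reproduce the
published coverage values closely.

## Known limitations

* Delta-method variances are first-order only; no second-order
  correction, no log-scale Wald variants.
* The fiducial constructions are the simulation-based approximate kind;
  no exact joint fiducial inference for functions of several rates.
* No bias correction for order-statistic estimators (RD/RR), no BCa or
  bias-corrected percentile variants.
* The aversion parameter defaults to ν = 3 and is swept nowhere; the
  engine accepts arbitrary J and K but ships presets only for the nine
  canonical 3 × 4 scenarios.
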