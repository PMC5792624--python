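# Methods

## Units, filtering and response

The unit of analysis is an Indian state or Union Territory. Two kinds of
record-level rules are applied before modelling:

- **Island exclusion.** Island UTs (flagged `is_island` in `units.csv`) have
  no road network connected to the mainland system and are dropped; a
  35-unit national table reduces to the 33 analysed units.
- **Railway-crossing deaths.** Deaths at rail level crossings involve a
  train as the striking vehicle and are removed year-wise when a
  `rail_deaths_YYYY` column is present (nationally they are 1–3% of on-road
  deaths in 2010–2012). Whether the source counts already exclude them is
  ambiguous in practice, so the subtraction is optional
  (`subtract_rail=False` turns it off) and defaults to subtracting whenever
  the columns are supplied.

The response is the unweighted arithmetic mean of the annual death counts
over exactly the configured analysis years (default 2010–2012, no
smoothing), which stabilises estimates for states with volatile counts
(Punjab's three years span a factor of 2.3). Because the Poisson likelihood
needs integers, the mean is rounded to the nearest integer when the design
is built; at the count magnitudes involved (tens to tens of thousands) the
rounding perturbation is far below Poisson noise. Fatality rates are
reported per 100,000 persons per year.

## Exposure construction

Census-style commute tables give worker counts per mode × one-way distance
bin. Each bin is represented by a single distance: closed-bin midpoints
(0.5, 3.5, 8, 15.5, 25.5, 40.5 km) and a configurable value for the open
>50 km bin (default 60 km). These representatives are deliberately
configurable rather than estimated: fitting within-bin distance-decay
averages is a separate estimation problem, and when externally estimated
averages exist they can be passed in wholesale. Distances are one-way
daily kilometres; no doubling for the return trip is applied because a
global factor cancels in mode shares and in relative risks.

Walking is structurally capped at the 6–10 km bin and cycling at the
21–30 km bin; violating counts are rejected at construction.

Because only a main mode is recorded, the walking legs of public-transport
trips would otherwise vanish. Every IPT/bus/train commuter in a bin beyond
0–1 km contributes `walk_per_trip` km of walking (default 1 km, covering
both trip ends; the sensitivity grid re-runs the final model at 0 and
1.5 km). Train *vehicular* distance never enters the regression — trains do
not run on roads — but train access walking does. The increment is applied
per commuter, not per trip leg.

Mode shares divide each mode's distance by the all-mode total (train
included by default); shares sum to one and are scale-invariant.

## Clustering

States are clustered on their 7-component share vectors with k-means
(scikit-learn's Lloyd algorithm, k-means++ seeding, 50 restarts, fixed
seed). Shares are already commensurate proportions, so no standardisation
is applied. k is chosen from the WSS curve: the smallest k whose WSS
reduction when moving to k+1 falls below 1% of the total scatter (the WSS
at the smallest scanned k, default scan 1–10). Normalising by total scatter
rather than the current WSS makes the rule scale-free and stops the scan
from chasing the roughly constant-proportion reductions that splitting any
finite cluster always yields. To keep the reported curve monotone, each
k+1 fit also warm-starts from the best k-solution's centroids plus its
worst-fitted point; Lloyd iterations never increase WSS from that start, so
WSS(k+1) ≤ WSS(k) holds by construction. Cluster profiles report the
arithmetic mean share vector and the median member fatality rate (even
clusters: mean of the central pair). Share–rate associations use Pearson
correlation; a constant column has no defined correlation and is reported
as missing.

## Hierarchical fatality model

For unit n with population e_n,

    y_n ~ Poisson(f_n)
    log f_n = log e_n + β₀ + β·X_n + δ_n
    δ_n ~ Normal(0, 1/τ_δ)
    log τ_δ ~ logGamma(shape 1, inverse-scale 0.0005)

The population offset (coefficient fixed at one) turns the linear predictor
into a log per-capita risk. δ_n is unstructured lognormal heterogeneity
(no spatial correlation is modelled). The log-Gamma prior on log τ_δ is the
exact transform of τ_δ ~ Gamma(1, rate 0.0005) — both parameterisations are
asserted equal in tests. Fixed effects carry Normal(0, variance 1000)
priors (configurable): effectively flat at the coefficient scales involved.

Covariate sets are nested: model 1 the six logged on-road distances (bus,
IPT, car, walk, cycle, 2W); model 2 adds logged diesel consumption (a
freight/taxi proxy); model 3 logged national-highway length; model 4
untransformed urban proportion and built-up density. Covariates are not
centred or standardised, so the intercept is a large negative log baseline
rate. Density is persons per built-up km² divided by 10,000 (configurable):
raw densities reach ~2×10⁵ and the rescaling keeps that coefficient O(0.1).
Diesel enters as the raw logged annual total, not per capita.

### Sampling

The posterior is sampled by an adaptive Metropolis-within-Gibbs kernel,
written for this model rather than taken from a PPL so that every piece is
unit-testable against independent oracles:

1. **Fixed-effect block.** Random-walk proposal with covariance from the
   Poisson-GLM (IRLS) curvature at the mode, global scale adapted to a
   23.4% acceptance rate during warmup (Robbins–Monro, decay t^−0.6).
2. **Heterogeneity.** The δ conditional factorises across units, so all n
   random-walk updates are vectorised with per-unit scales adapted towards
   44% acceptance.
3. **Interweaving recentring.** The likelihood depends on (β, δ) only
   through ξ = β₀ + Xβ + δ. Holding ξ fixed, the conditional of β given
   (ξ, τ_δ) is exactly Gaussian — the δ prior acts as a ridge regression of
   ξ on the design — and is drawn exactly:
   β ~ N((τX'X + I/σ²_prior)⁻¹ τX'ξ, (τX'X + I/σ²_prior)⁻¹), δ = ξ − Xβ.
   Without this step the tight β|δ conditional (Poisson information at
   count magnitudes of 10²–10⁴) makes conditional schemes mix at R-hat ≈ 2;
   with it, fixed-effect ESS exceeds 1,000 per 2,000 draws.
4. **Precision.** τ_δ | δ ~ Gamma(1 + n/2, 0.0005 + ½Σδ²), exact conjugate
   draw.

Defaults: 4 chains, 2,000 warmup + 2,000 kept draws each, chain seeds
spawned from a single user seed (runs are bit-reproducible). Initialisation
jitters around the IRLS mode. Convergence is flagged (not enforced) when
any fixed effect has split R-hat > 1.05 or bulk ESS < 400 (computed with
arviz); summaries are posterior means, SDs and equal-tailed quantiles at
2.5/5/50/95/97.5%. Significance marks: 95% if zero lies outside
[q2.5, q97.5], else 90% if outside [q5, q95].

Degenerate inputs: logged covariates must be strictly positive (zero
distances are an error naming the unit and covariate); the sampler refuses
designs with fewer than p+2 units; likelihood overflow at extreme linear
predictors returns −∞ (a structurally impossible state), while non-finite
parameters raise.

## Scenario engine

A scenario moves `step_pp` (default 0.5) percentage points of share per
step from one mode to another, total conserved, over `n_steps` (default 10,
baseline included). Expected fatalities follow the fitted multiplicative
form, so RR = Π (share/baseline)^e with the rounded published exponents by
default and a full-precision switch that changes RR in the third decimal.
A step that would drive the source share negative (or to exactly zero with
a non-zero exponent, where the power law is undefined) truncates the curve
at the last valid step. Walking generated by bus trips is not recomputed
inside scenarios; shares shift vehicular totals only.

Geometry: log RR of a two-mode shift is concave in the shifted fraction
(both second-derivative terms are negative), so a shift between two
positive-exponent modes (2W→car) yields a monotone rise, a monotone
decline, or a rise to an interior peak — the critical mix beyond which
further car adoption lowers deaths. Car-rich baselines (car:2W ≈ 1.3+) are
past that point and decline; car-poor ones (ratio ≤ 0.5 with a large 2W
share) rise throughout. A convex "U" cannot occur under this model;
`detect_turning_point` therefore reports interior minima for generic curves
and interior maxima (`kind="max"`) for the scenario-A critical point.
Shifts from a negative-exponent mode to a positive one (walk→2W, cycle→2W)
are strictly increasing whenever both shares stay positive.

## Synthetic data

The generator emulates the study's data shape with every constant surfaced
as a parameter:

- ~33 units; total workers per unit log-uniform on [10⁴, 5×10⁶];
  populations log-uniform on [2.4×10⁵, 2×10⁸]; diesel on [48, 7,483]
  thousand tonnes; highway length on [15, 7,874] km; urbanisation uniform
  on [10%, 98%]; built-up density log-uniform on [500, 50,000] persons/km²
  (within the observed [258, 226,066] span but clear of the extremes for
  numerical head-room). These ranges span the magnitudes observed across
  Indian states so large offsets and wide covariate scales are exercised.
- Mode structure: a target distance-share vector per unit is drawn from a
  Dirichlet centred on an assigned centroid (concentration 300 for planted
  clusters; a looser 30 around an all-India-like prior otherwise); worker
  counts per mode are set so realised distance shares match the target,
  then spread over bins by a distance-decaying multinomial honouring the
  walk/cycle caps.
- Counts: δ_n ~ N(0, σ_δ²) with σ_δ = 0.3 by default, f_n = e_n·exp(β₀ +
  βX_n + δ_n), and three independent Poisson yearly draws emulate the
  three-year averaging path (`poisson_noise=False` substitutes f_n exactly
  for arithmetic round-trip checks). When β₀ is not given it is calibrated
  so the mean fatality rate lands at 11.6 per 100,000 — the observed
  all-state average. Expected counts above 10⁹ abort as out-of-range.

Not emulated: proxy-respondent and under-reporting biases, multimodal trips
collapsed to a main mode, and spatial correlation between neighbouring
states. Passing recovery tests therefore demonstrates correctness of the
estimator under the model's own assumptions, not robustness to those
real-data pathologies.

## Calibration evidence and problem sizes

`roadrisk.recovery.coverage_experiment` simulates fresh studies and refits
the full hierarchy. At the study's own scale (33 units, σ_δ = 0.3,
final-model-like planted coefficients, 200 replicates, 2 chains × 750
warmup + 750 draws — draw counts chosen so the whole experiment runs in a
couple of minutes while quantile Monte-Carlo noise stays far inside the
reported bands) the equal-tailed 95% intervals cover each planted
coefficient 90–96% of the time and posterior means fall within three
posterior SDs of truth in ≥97.5% of replicates. Single-fit checks include
a dense-grid quadrature oracle for the intercept-only model (agreement of
posterior means within 0.02), an independent Newton/IRLS Poisson-GLM
oracle for the τ→∞ limit (mode agreement within 10⁻³), exact term-by-term
density agreement with scipy distributions, and the offset contract
(scaling populations by 10 shifts the intercept by −log 10).

## Known limitations

- Ecological design: state-level associations need not hold at district or
  city level (modifiable areal unit problem), and commute distance proxies
  total travel.
- The elbow rule is a heuristic; the full WSS curve is always returned for
  inspection.
- Scenario RR is a point prediction from posterior-mean exponents;
  posterior uncertainty bands around RR curves are not computed by default.
- The sampler is tuned for this model family (counts with a population
  offset, modest p); it is not a general-purpose MCMC engine.
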