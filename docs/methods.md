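# Methods

## The model

`memstep` implements discrete-time step-selection analysis (SSA) with
spatial-memory ("familiarity") covariates. The probability of observing an
animal at location $s_t$ given its movement history $H_{t-1}$ factorizes into
a selection-free movement kernel, a movement-free habitat-selection weight,
and an exponential familiarity weight:

$$
p(s_t \mid H_{t-1}) \;=\;
\frac{k(s_t \mid H_{t-1};\,\beta_m)\; e^{\beta_w^\top r(s_t)}\;
      e^{\beta_f^\top f(s_t;\,H_{t-1})}}
     {\sum_{s' \in U} k(s' \mid H_{t-1};\,\beta_m)\;
      e^{\beta_w^\top r(s')}\; e^{\beta_f^\top f(s';\,H_{t-1})}}
$$

* $k$ — gamma-distributed step lengths (shape, scale in meters) times a
  von Mises turning-angle distribution with mean 0 and concentration
  $\kappa$. Both are exponential-family so kernel corrections can be
  absorbed by the fitted model through the movement-adjustment covariates
  $\log sl$, $sl$, $\cos ta$ (included by default, removable for a strict
  kernel-times-selection fit).
* $r(s)$ — environmental covariates sampled from rasters at the step
  endpoint.
* $f(s; H)$ — the familiarity covariates below.
* The continuous normalizer over the domain $U$ is approximated by the
  standard used + available discretization, so estimation reduces to
  conditional logistic regression with one stratum per observed step.

## Familiarity covariates

**Occurrence distribution (OD).** An isotropic Gaussian kernel density of
the fixes within a stated past window, evaluated at grid-cell centers and
normalized to total mass 1. Windowing encodes abrupt forgetting: fixes
inside the window count equally, older fixes not at all; a window spanning
the whole track encodes a never-forgetting animal. The OD is recomputed at
every stratum by default, with a `stride` option to reuse it between
updates. Continuous-time conditional densities and residence-time bridge
estimators used in some applications are deliberately out of scope; the
model consumes the OD surface generically, so the KDE is a drop-in stand-in
whose bandwidth defaults to `max(res, 0.5 * median step length)` when not
given.

**Contour indicator.** Binary membership of the smallest-density set of
cells whose cumulative OD mass reaches a level (e.g. 0.95), accumulated in
descending-density order with ties broken by row-major cell index for
determinism. This is the "previous-season range" form of the OD covariate.
The density-contour reading (rather than per-cell presence/absence of
fixes) is used because the contour is defined on the estimated OD surface.

**Diel-stratified short/long ODs.** Four surfaces per stratum — long-term
(all history), short-term (last `short_window` days, default 3), and the
same two restricted to past fixes in the focal step's diel phase. Day is
the hour-of-day interval `[6, 18)` by default; the boundary is a free
choice and configurable. A stratum whose requested surface has no history
yet is skipped (flagged unavailable), not zero-filled: "no information" and
"zero intensity" are different states.

**Time since last visit (TSLV).** A per-cell clock: each fix stamps its
grid cell with the visit time; the covariate at a candidate endpoint is the
stratum time minus its cell's stamp. Visits are cell-level (default 2000 m
cells), so "revisitation" happens anywhere within the perceptual vicinity
of a previously used place rather than at exact coordinates. Never-visited
cells report a fixed default of 365 days — as if last seen a year before
the record began. TSLV grows without bound for long-unvisited cells; the
default applies only to never-visited ones (a deliberate choice — capping
visited cells at the default would erase the distinction between "long
ago" and "unknown"). Selection on TSLV is modeled with linear + quadratic
terms; a negative quadratic coefficient implies a preferred return time
at the vertex $-\beta_1 / (2\beta_2)$ days.

**Burn-in.** With real data the animal's history before the record is
unknown, so an initial period (e.g. the first year) can be sacrificed to
populate the visit map before any stratum is emitted. In the synthetic
studies here burn-in is 0: the simulator itself starts from an empty memory
(all cells at the default), so the generating covariate process is known
exactly from $t_0$ and discarding data would only inflate standard errors.

**Migration predictors.** (i) Minimum Euclidean distance from a candidate
endpoint to the previous season's migration path (point-to-segment over the
polyline); a negative coefficient attracts the animal onto its old route.
(ii) The cosine of the angle between the candidate step and the direction
from the step's start to a remembered range centroid (+1 straight toward,
-1 straight away); the centroid is the arithmetic mean of the remembered
range's locations. The cosine depends only on step direction, never length.

## Fitting

The conditional-logistic (stratified softmax) log-likelihood
$\sum_s [\eta_{used} - \log \sum_j e^{\eta_j}]$ is implemented directly
with per-stratum log-sum-exp stabilization and maximized by damped Newton
iteration using the analytic gradient and observed information. The
likelihood is concave; Newton steps are capped at max-norm 10 and halved
until the likelihood does not decrease. Convergence is declared when the
gradient max-norm falls below `tol` (default 1e-8) or the affine-invariant
Newton decrement becomes negligible — the latter matters because TSLV and
TSLV² columns differ by five orders of magnitude in scale, and Newton
itself is affine-invariant, so no standardization is performed. The
coefficient covariance is the inverse observed information at the optimum;
inference is per-coefficient Wald. A saturated likelihood (every used
probability near 1, coefficients diverging) is reported as non-convergence
with a complete-separation diagnostic rather than an error or a bogus fit.
A term constant within every stratum is rejected as inestimable.

Relative selection strength between two locations differing in stated
covariates is $RSS(x_1, x_2) = \exp\{\beta^\top (x_1 - x_2)\}$, with an
optional Wald interval computed on the log scale.

## Strata construction

Each observed step with a defined turning angle becomes one stratum: the
used endpoint plus `n_avail` (default 20 — conventional SSA practice)
available endpoints drawn from the tentative kernel at the same start and
previous bearing. Tentative kernel parameters are fitted once from the
observed steps by ML (gamma on step lengths with zero step lengths replaced
by half the smallest positive value so strata stay aligned; von Mises
$\kappa$ with mean fixed at 0, solved from the mean cosine and capped at
700 where Bessel evaluation would overflow). Available turning angles are
drawn from the fitted von Mises by default (a uniform proposal is available
via $\kappa = 0$). Memory covariates are *replayed*: a stateful provider is
queried for covariates at the candidate endpoints using history strictly
before the step's end, then advanced with the step actually taken —
through every fix, including burned-in ones. The replay uses the same
primitives and update cadence as the forward simulator, so replayed values
match the simulator's internal diagnostics exactly (this is asserted, not
assumed). Candidates falling outside the raster domain are dropped from the
stratum, matching the simulator's zero-weight truncation.

## Forward simulation

No forward-simulation protocol is standard in this literature (memory SSAs
are usually only fitted), so the simulator's conventions are this package's
own. Each step draws $M$ = 200 candidates from the kernel (an importance
sample, so the kernel factor lives in the proposal), weights them by
$\exp(\beta_w^\top r + \beta_f^\top f)$, normalizes, samples one, then
advances the memory state (OD buffer append/refresh, TSLV stamp). The
$M$-candidate choice set approximates the continuous normalizer; a
convergence check (doubling $M$ changes aggregated one-step probabilities
by well under 1% total variation) backs the default. Boundary handling is
zero-weight truncation — reflection was rejected because it distorts the
turning-angle distribution; if every candidate falls outside the domain the
step is redrawn once, then errors. All randomness flows from one seeded
generator, so identical config + seed gives bitwise-identical tracks.

## Synthetic scenarios

The scenario generator provides the study conditions for all quantitative
tests; real applications of these models run on proprietary telemetry, so
validation is by parameter recovery at known truth. Landscapes are
stationary Gaussian random fields (seeded white noise smoothed under
periodic boundaries, rescaled to the target variance). Conditions are fixed
once per scenario:

| scenario | memory covariate | key conditions |
|---|---|---|
| `bear_like` | TSLV + TSLV², vertex 180 d | 2000 m cells, 365 d default, 4 h fixes, 3000 steps, $\beta_{tslv}=0.018$, $\beta_{tslv^2}=-5\times10^{-5}$ |
| `hog_like` | last-3-days OD density | 100 m cells, 2 h fixes, 1500 steps, bandwidth 150 m, $\beta_{od}=50$ |
| `crane_like` | previous-season 95% OD contour (binary) | previous season simulated kernel+habitat walk, 1 h fixes, 2000 steps, $\beta=1$ |
| `deer_like` | distance-to-path + centroid cosine | 100-vertex wiggly route between ranges, $\beta_{dist}=-0.002$ per m, $\beta_{cos}=1.5$ |

All scenarios include a habitat field with $\beta_w = 0.3$ where a raster
domain exists. OD covariates enter as raw density on a surface summing
to 1, so their coefficients are large in absolute value (a density contrast
of 0.02 at $\beta = 50$ contributes 1 to the linear predictor); Newton
fitting is scale-invariant, so no rescaling is needed.

What the generator does *not* emulate: fix loss and irregular sampling,
location error, behavioral-state switching, multi-animal interactions,
habitat-memory confounding (the landscape is independent of the remembered
structures by construction), and geographic coordinates. Passing recovery
tests therefore demonstrates the estimator is correct for its own
generating model — the minimum requirement any fitting pipeline must meet —
not that memory effects are identifiable in any particular field dataset,
where unmodeled habitat can masquerade as familiarity.

## Validation studies and problem sizes

The studies in `memstep.validation` (run by `scripts/acceptance.py` and the
acceptance test suite) use these sizes, chosen to finish in minutes on one
CPU:

* likelihood oracle: 10 strata x 5 candidates vs pure-python softmax
  enumeration; null closed form $-S\log(J+1)$ at $S=500, J=20$;
* recovery: 20 independent replicates each of `bear_like` (3000 steps, 20
  availables) and `hog_like`; a replicate succeeds when every generating
  coefficient lies within 3 SE of its estimate;
* Wald coverage: 100 replicates of 500 strata x 21 candidates simulated
  directly from the choice model, two coefficients;
* site fidelity: 10 paired seeds, 1000-step walks under the OD-forager
  generating conditions (last-3-days window, attraction coefficient 50) vs
  a zero-coefficient control at the same seed, compared by 95% minimum
  convex polygon area (hull of fixes after dropping the 5% farthest from
  the centroid). The domain is sized (19.2 km) so the control walk
  essentially never meets the boundary — truncation would cap both arms'
  ranges and confound the comparison. An all-history OD was considered and
  rejected for this study: spreading the density mass flattens the local
  gradient that drives attraction, weakening the very effect under test;
* memory replay: 400-step TSLV walk replayed offline, compared exactly;
* geometry: 1000 random point/path draws vs brute-force segment
  enumeration;
* null walk: 5000 steps, zero coefficients, Kolmogorov-Smirnov tests of
  realized step lengths and turning angles against the generating kernel at
  $\alpha = 0.01$.

## Numerical choices and degenerate inputs

* Turning angles live in $(-\pi, \pi]$, counterclockwise positive; the wrap
  maps $-\pi$ to $\pi$.
* Time is decimal days from a track-local epoch (midnight of the first fix
  for datetime input), so hour-of-day falls out of the fractional part; no
  timezone machinery.
* Gaps are kept and flagged with their duration (`gap_days`); no
  interpolation, splitting, or resampling to a common fix interval — that
  choice is left to the user because any default would silently change the
  movement kernel.
* Coordinates must be projected planar meters.
* OD with an empty window errors; a diel OD stratum with no history is
  skipped.
* `od_contour_indicator` at level 1.0 marks exactly the positive-density
  cells; ties broken row-major.
* Grid cells are half-open `[edge, edge + res)`; a point on the shared edge
  of two cells belongs to the one with the larger index.
* The von Mises density uses exponentially scaled Bessel functions and is
  exact up to the $\kappa = 700$ cap.

## Known limitations

* The KDE occurrence distribution ignores serial autocorrelation in fixes
  (a movement-model-based OD would not) and its bandwidth is a free choice.
* Memory-decay shape is fixed by the covariate choice (rectangular window
  for ODs, linear clock for TSLV); smooth decay rates cannot be estimated —
  that requires jointly estimated mechanistic models outside this scope.
* One individual at a time; no hierarchical pooling across animals.
* OD updates at `stride` > 1 reuse a slightly stale surface; the default
  updates every step/stratum.
* The truncated (zero-weight) boundary slightly distorts the realized
  kernel near domain edges; fitting is consistent because the replay
  truncates identically.
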