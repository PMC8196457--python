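# Methods

This note documents the models behind `ruttrack`, the defaults that matter,
what the synthetic generator does and does not emulate, and the design
choices made where more than one defensible option existed.

## Data model and dyad alignment

Tracks are ordered relocations (`animal_id, sex, study_area, timestamp, x, y`)
with projected metric coordinates; the package performs no geographic
reprojection, because every threshold in the analysis (100 m proximity, 30 m
cells, 10 m GPS error) is metric. Dyads are formed by nearest-time matching
of two tracks' fixes: candidate pairs within a tolerance (default **300 s**)
are accepted greedily in order of increasing time difference, each fix used
at most once. Nominally "simultaneous" GPS schedules drift by minutes in
practice; 300 s accepts that drift while never pairing fixes an hour apart.

Breeding-phase calendars are year-agnostic (month/day) per region:
north — Oct 18–Nov 7 (early), Nov 8–Nov 28 (peak), Nov 29–Dec 19 (late);
south — Oct 16–Nov 5, Nov 6–Nov 29, Nov 30–Dec 20. Interval endpoints are
inclusive and the three phases partition each season exactly.

## Interaction events

The liberal rule marks a dyad fix pair "close" at distance ≤ 100 m, requires
at least `min_run = 2` consecutive close fixes (one hour at hourly sampling),
and splits events where the pair was beyond 100 m for more than
`gap_hours = 2`. Far fixes inside a merged span remain event fixes, and a
merged candidate must still satisfy **mean** distance ≤ 100 m over all its
fixes. If a far excursion pushes a merged span's mean over the threshold,
the span is re-split into its constituent close runs, each re-checked alone
— discarding the whole span would let a single distant hour erase an
otherwise valid multi-day tending bout.

The dynamic-interaction statistic per simultaneous step is
`DI_t = f_t · g_t` with `f_t = cos(θ_a − θ_b)` (azimuth agreement) and
`g_t = 1 − (|d_a − d_b| / (d_a + d_b))^α` (displacement similarity, α = 1).
Degenerate steps: both animals stationary → `DI_t = 1`; exactly one
stationary → `DI_t = 0`. These conventions use exact float zeros; GPS-noise
data essentially never triggers them, but idealized inputs do. The
conservative filter keeps events with mean DI **strictly** greater than 0.5.
DI is computed on the raw paired fixes, not regularized ones: regularization
smooths both tracks toward their own bridge means and would bias DI upward.

Limitation worth knowing: at slow (tending-like) speeds the observed-step
azimuths are noise-limited — 10 m GPS error on ~50 m hourly steps perturbs
each azimuth by ~0.3 rad — so genuinely cohesive pairs can fall below
DI = 0.5 on short events. The conservative set is therefore a strict subset
biased toward longer, faster cohesive events.

## Brownian bridge movement model

The motion variance `σ²_m` (m²/s) is estimated by leave-one-out maximum
likelihood: every second interior fix `z_k` (odd indices by default; the
even-index alternative is available and differs negligibly) is predicted
from its neighbors as `N(z_{k−1} + a(z_{k+1} − z_{k−1}), s² I)` with
`a = (t_k − t_{k−1})/T`, `T = t_{k+1} − t_{k−1}` and per-coordinate variance
`s² = a(1−a)T σ²_m + (1−a)²δ² + a²δ²`, `δ` the fixed GPS error SD (10 m).
The 1-D bounded search covers `[1e−12, 1e4]` m²/s. With a single triplet and
`δ = 0` the maximizer has the closed form `r²/(a(1−a)T)` (mean squared
per-coordinate residual), which the tests verify to 1e−6 relative.

The UD raster (default **30 m** cells) is the time-weighted average over
bridges of the bridge Gaussian, discretized at `n_integration = 10` equally
spaced interior time points per bridge, evaluated at cell centers (Gaussians
truncated at 5 SD), and renormalized to unit mass. The grid buffer defaults
to `max(300 m, 3.5 × max bridge SD)`; a smaller explicit buffer warns about
clipped mass. No maximum bridge lag is imposed by default — all
consecutive-fix bridges are used — since hourly data rarely contain gaps
long enough to matter; `max_lag` is available where they do. Per-season and
per-phase UDs are separate full refits of `σ²_m` on the subset.

The percent-volume transform ranks cells by density and assigns each cell
100 × the cumulative mass of all cells at or above its density; tied
densities share the inclusive value, matching "greater than or equal to"
contour semantics. Point lookup uses half-open cells
`[edge, edge + cell)`; points outside the extent report NaN with a warning
rather than failing, so a stray fix cannot abort an evaluation run.

## Hourly regularization

The state model needs locations on a strict hourly grid. A continuous-time
Bayesian functional movement model could provide posterior-mean hourly
locations, but its configuration (basis, priors, autocorrelation parameter)
admits many choices and the downstream HMM consumes only point estimates, so
`ruttrack` uses a deterministic Brownian-bridge Gaussian smoother with the
same contract: each interior fix is shrunk toward the linear interpolant of
its neighbors with weight `v/(v + δ²)`, `v = a(1−a)T σ²_m` the local bridge
variance, then hourly estimates take the bridge conditional mean (linear in
time) between smoothed fixes. With `δ = 0` the output interpolates the
observations exactly; with hourly deer-scale data and `δ = 10` m the
estimates move at most a few meters. The process variance comes from the
BBMM fit for the same animal (a moment estimate of the diffusion rate is the
fallback). Hours inside observation gaps longer than 12 h are flagged
`imputed` but retained. No posterior uncertainty is propagated — a known
simplification; the HMM treats the hourly estimates as data.

## Hidden Markov model

Observations per hourly transition are step length (m) and turning angle
(radians, signed azimuth change wrapped to (−π, π], missing at the series
start and next to zero-length steps). Each state emits steps from a
zero-inflated gamma — a point mass `π0_s` at exactly zero plus a gamma with
mean `μ_s` and SD `σ_s` — and angles from a von Mises with mean `m_s` and
concentration `κ_s`. The point mass exists because the gamma density is
undefined at zero and real GPS series contain exact repeats; for smoothed
hourly data `π0` fits near zero and is harmless.

Fitting maximizes the exact forward log-likelihood (log-space scaled,
numba-compiled) directly with L-BFGS-B on working-scale parameters: log
means and SDs, logit zero mass, the angle mean as an `atan2(b, a)` pair, log
concentration, and row-wise multinomial logits for the transition matrix.
Each individual's series contributes an independent likelihood term started
at the stationary distribution of the shared transition matrix — all
parameters are pooled across individuals, which assumes little individual
variation. Multi-start (default 25 restarts; smaller values are used in
tests for speed) seeds initial step means at randomized quantiles of the
pooled positive steps — the randomization ranges into the far tail (up to
q0.998) because rare states such as brief traveling bouts are unreachable
from bulk quantiles. States are canonically reordered by ascending step mean
after fitting. Decoding is exact Viterbi; ties break toward the lower state
index, and missing angles drop the angle factor. Each hourly location
carries its outgoing step's state, with the final location repeating the
last state.

No model selection is performed across state counts: 2- and 3-state models
are both fit and both reported, since selecting the number of HMM states is
unreliable and the evaluation question is whether *either* flags events.

## Evaluation layer

Event hours are all hourly timestamps between an event's start and end,
inclusive. The UD diagnostic looks up each event fix's percent-volume value
in the animal's own (single-sex) volume grid and reports per-event means
plus a sweep over candidate contour thresholds v ∈ {5, 10, …, 95}: the
fraction of event locations with volume ≤ v (male convention — events in
core areas) and ≥ v (female convention — events on excursions). The HMM
diagnostic reports per-event state proportions, the modal state (ties to the
lower index), and the **modal-state agreement index**: the largest fraction
of events sharing one modal state. A permutation baseline re-places each
event as a same-length contiguous block uniformly at random in its animal's
decoded sequence (999 permutations) and recomputes the agreement, giving the
null distribution under "states carry no event information". The threshold
sweep, agreement index and permutation baseline operationalize what is
otherwise a visual histogram judgment; reports label them as artifact
extensions accordingly.

One caveat on the sweep: the volume of a randomly chosen time point is
approximately uniform on (0, 100] by construction (the volume transform is a
probability-integral transform of time spent), so the v = 95 column is
expected to "capture" ~95% of locations even under the null; conclusions
should rest on the shape of the sweep below ~90, and the package's own
negative-control checks do exactly that.

## Synthetic generator

Each animal follows `x_{t+1} = x_t + β(c − x_t) + N(0, σ² I)` hourly around
a home-range center, with defaults β = 0.1, σ = 130 m chosen so
season-scale 95% home ranges are roughly 1–3 km² (typical deer scale; a
realism default, not a validated quantity). Observed fixes add N(0, (10 m)²)
GPS error. Event schedules default to 10 non-overlapping events per season
with log-normal durations (median 7 h, log-SD 0.9) truncated to [1, 79] h.
All randomness derives from one seed through named `SeedSequence` spawns
(schedule / paths / observation noise), so identical seeds give bit-identical
output and stages can be regenerated independently.

Event modes:

* **cohesive-distinct** (positive control): the female anchors at her
  event-entry point with reduced diffusion (default 40 m/h — a
  quasi-stationary tending pace) and the male holds an AR(1) tether to her
  (stationary SD 25 m, persistence 0.95 per hour). Proximity *and* changed
  movement. The tending pace trades off two detectabilities: slower movement
  sharpens the state contrast for the HMM but makes raw-fix DI noise-limited
  (see above); 40 m/h keeps both the DI filter and the state model working,
  and is the realistic order for tending ungulates. The mode produces three
  genuine movement regimes — ranging (~170 m steps), tending (~50 m), and
  the travel steps into and out of events (hundreds of meters) — so the
  3-state model is the correctly specified detector for it; 2-state modal
  agreement is lower through model-order mismatch, not through any failure
  of the decoding. Entry/exit appear as single large steps rather than a
  gradual approach — a simplification that slightly inflates the travel
  state's step lengths.
* **cohesive-null** (negative control): the male keeps his baseline dynamics
  entirely untouched and the *female* tethers to him during events, so the
  male's event-hour step/turn distributions equal his non-event ones exactly
  by construction. (The description "male tracks the female" with matched
  male marginals is realized with the coupling direction reversed — this is
  the only construction that guarantees the matching exactly rather than
  approximately.) The female teleports to the male at event entry; her
  marginals are not preserved and are not the tested quantity.
* **stationary-female**: the female freezes and the male orbits within 50 m
  (one loop per 12 h, 5 m jitter) — the sit-and-wait caricature used to test
  UD lookups at a range core.

What the generator does **not** emulate: landscape and resource covariates,
multi-male competition, hunting disturbance, fix loss and irregular
schedules, and individual heterogeneity in movement parameters. Passing
tests therefore demonstrate correctness of the pipeline's logic and its
behavior under clean, known conditions — not that the single-sex methods
would or would not work on any particular field dataset.

## Numerical choices

* Motion-variance search: bounded scalar minimization, `xatol = 1e−12`.
* UD: Gaussians truncated at 5 SD; mass renormalized after rasterization.
* Forward algorithm: per-step max-shift scaling; underflow of the scaled
  state vector returns −∞ so degenerate restarts are rejected, not crashed.
* Transition-matrix logits are row-centered before softmax for overflow
  safety; the stationary distribution solves the fixed-point system by least
  squares with a sum-to-one row.
* Viterbi and modal-state ties break toward the lower state index,
  deterministically.
* Degenerate inputs: tracks need ≥ 2 fixes (UD), ≥ 3 (variance fit, series
  construction); zero-duration bridges are skipped; empty dyad overlap is an
  empty result, not an error.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 100 random 20-fix series for
detector-oracle agreement; exhaustive path enumeration at T ≤ 8; 20
simulated 500-fix paths for motion-variance recovery; 10 runs of 2,000 steps
(6 restarts) for HMM recovery; 6 positive-control and 3 negative-control
season-length scenarios (8 restarts, 999 permutations). These sizes give
stable aggregate statistics in minutes on one CPU; the package defaults
(25 restarts) are higher than the test settings.
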