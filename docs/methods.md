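# Methods

## The problem

Liver-transplant candidates in the United States are ranked by the MELD
score (Model for End-Stage Liver Disease, allocation scale 6–40). A
registrant whose MELD rises sharply may be at materially higher risk of
*waitlist dropout* — removal because they died, became too sick, or were
deemed medically unsuitable — than a registrant who arrived at the same
MELD gradually. This package implements the full analysis needed to study
that question and to fold short-term MELD dynamics into a composite
prioritization score:

1. a synthetic waitlist-registry generator with the statistical structure
   the analysis assumes;
2. cohort rules and outcome coding for a competing-risks design (dropout
   vs transplantation);
3. the ΔMELD₃₀ statistic and its threshold indicators;
4. cause-specific Cox models on counting-process data, including MELD-
   stratum × jump interactions and Harrell's C-index;
5. composite scores by linear-predictor equating;
6. landmark Aalen–Johansen calibration of observed vs predicted dropout.

## The ΔMELD₃₀ statistic

For a record at day *t* with uncapped MELD *m*, let *W* be the prior
records dated in [*t* − 30, *t*). If the immediately preceding record lies
in *W* (gap ≤ 30 days),

    ΔMELD₃₀ = m − max{ MELD(r) : r ∈ W },

a rise relative to the best (highest) recent score. If the preceding
record is older than 30 days, the raw change is scaled per 30-day
interval, ΔMELD₃₀ = (m − m_prev) / ⌈gap/30⌉. Every registrant's first
record has ΔMELD₃₀ = 0. The statistic is computed on *uncapped* MELD so
that movement above the allocation cap of 40 remains visible. Alongside
it we record `n_meas_30` (records in the trailing 30-day window, current
record included), indicators at +5 and +10 points, and a ≥ 30 % relative
rise indicator.

Conventions worth making explicit (the definition leaves them open):

* **Sign.** The delta is *current minus prior-window max*, so a rise is
  positive and "ΔMELD₃₀ ≥ 10" denotes deterioration. The current record
  is excluded from the window max (otherwise the delta could never be
  positive) but counted in `n_meas_30`.
* **Boundary.** A gap of exactly 30 days uses the within-window rule;
  the ⌈·⌉ divisor exceeds 1 exactly when the gap exceeds 30 days.
* **30 % baseline.** The relative-rise indicator uses the same baseline
  as the delta itself (window max, or previous record when gap-scaled).
  Literature variants use the listing MELD; that choice is not exposed
  because no downstream result here depends on it.

A stateless brute-force implementation (`delta_features_single`) rescans
all prior records on every call and serves as the oracle for the
incremental engine; equality is asserted feature-by-feature on 10,000
random irregular trajectories.

## Synthetic registry generator

Each registrant receives demographics (age ~ N(52.8, 10.4²) truncated at
18; ethnicity and diagnosis from registry-like frequencies), a listing
MELD from a discretised bell centred near 14, and a latent *jump-prone*
class (25 % of registrants) with lower mean serum sodium (133 vs 137.5
mEq/L, σ = 4) and a 2.5× jump-probability multiplier — sharp MELD rises
co-occur with hyponatraemia.

Lab visits arrive with log-normal gaps (generative median 25 days,
σ = 1.0). Because gaps cut short by an event or the administrative
horizon are preferentially long ones, the *observed* median inter-record
gap is ~23 days with ~90 % of gaps within three months, which is the
registry cadence the analysis assumes. Between visits the uncapped MELD
takes a rounded Gaussian step (σ = 1.6) or, with a MELD-dependent
probability rising from 1 % to 23 % per visit, a jump of 10 + Poisson(2)
points.

Dropout and transplantation compete as cause-specific exponential
hazards, piecewise-constant between visits:

    λ_k(t) = h_k · exp( β_k,MELD · (MELD_capped − 20) + β_k,jump(stratum) · J(t) )

with J(t) the ΔMELD₃₀ ≥ 10 indicator computed from the record history at
the latest visit — i.e. the generative covariates are *exactly* the
covariates the downstream fit sees, so injected log-hazard ratios are
recoverable without approximation bias. Default effects: MELD log-HR
ln 1.2 per point for dropout (ln 1.12 for transplant) and per-stratum
jump log-HRs declining over MELD strata 16–20 … 36–40 (dropout HRs
3.81 → 1.52, transplant 3.89 → 1.65). Baseline rates (dropout
7.5 × 10⁻⁴/d, transplant 1.7 × 10⁻³/d at MELD 20, censoring
1.2 × 10⁻⁴/d, horizon 900 d) were calibrated once against registry-level
structure: ~48 % transplanted, ~25 % dropout, ~4 % removed improved,
~22 % still waiting, ~12–13 records per registrant. Registrants
event-free at the horizon receive an explicit last-seen record there, so
censoring in the counting process is exact rather than truncated at the
final lab visit (which would discard event-free exposure and bias
hazards upward).

`jump_effect_days` controls the persistence of the post-jump hazard
boost. With the default 0 the boost tracks the observed indicator
exactly (it lapses when the jump leaves the 30-day window) — the right
setting for parameter-recovery studies. The policy-era scenarios set it
to 180 days: landmark calibration curves only reproduce the
characteristic elevated-dropout pattern if a sharp rise marks a
registrant as persistently sicker over the 1–6 month evaluation window,
which is what the real-data curves show. This is the single deliberate
divergence between the generative hazard and the fitted covariate set,
and it is why the policy scenarios are unsuitable for coefficient
recovery (the fitted jump coefficients are attenuated there).

Named scenarios:

* `recovery_scenario` — jump probabilities raised to 8–18 % across all
  MELD bands (sparse strata would otherwise have no jump events at desk
  scale), no inactive rows, no exception flags, `jump_effect_days = 0`.
* `pre_policy_scenario` — realistic rare jumps, persistent (180 d) jump
  effect, stratum-declining dropout HRs 3.81 → 1.52; n = 12,000 by
  default because jump-stratum landmark cohorts are thin when jumps are
  rare.
* `post_policy_scenario` — as above but the jump effect is zero below
  MELD 31 and moderate above (HR 1.8/2.2), emulating the current policy
  era in which sodium-driven jumps no longer carry excess dropout risk
  at low MELD.

What the generator does **not** emulate: exception points, Status 1,
organ-offer mechanics and geography, measurement error in MELD
components, informative visit timing (sicker patients measured more
often — visit gaps here are independent of state), and secular trends.
Passing tests therefore demonstrate the pipeline's correctness under the
stated generative model, not the truth of any clinical claim about real
registries.

## Cohort construction

Rules are applied registrant-wise in a fixed order so exclusion tallies
are reproducible: listing window → age < 18 → exception/Status-1 flags →
unknown status codes → single entry → inactive-row removal → single
entry re-applied (dropping inactive rows can leave a lone record).
Outcomes: a final record coded died / too-sick / medically-unsuitable is
*dropout*; transplanted is *transplant*; everything else (including
removal for improvement) is censoring at the last record. Time zero is
each registrant's first retained record (time-on-list); a
time-from-listing variant would differ only when early rows are
filtered.

Each registrant is expanded to half-open (start, stop] intervals with
covariates frozen at the interval-opening record and cause-specific
event indicators on the final interval only — the standard
counting-process representation. The competing cause is a censoring by
construction (its indicator stays 0).

## Cause-specific Cox engine

The fitter maximises the counting-process partial likelihood by
Newton–Raphson with step halving, Efron (default) or Breslow ties.
Risk-set sums use suffix cumulative sums over rows sorted by interval
start and stop (risk set {start < t ≤ stop} = {stop ≥ t} \ {start ≥ t}),
so an iteration costs O((n + e)·p²). Covariates are centred internally;
the stored Breslow baseline is re-referenced to covariates = 0.
Convergence is |Δ log L| < 10⁻⁹ (default) within 50 iterations.

Degenerate inputs fail loudly: zero events for the requested cause;
constant covariates; a singular information matrix (the collinear terms
are named via the null eigenvector); monotone likelihood / separation,
detected after convergence as a coefficient and standard error that are
both huge on the standardised scale (|β|·sd > 10 and se·sd > 10).

Correctness is anchored three ways: a brute-force enumeration of every
risk set on small fixtures (grid-search maximiser agreement to 10⁻⁶);
Efron ≡ Breslow identity on tie-free data; and a frozen fixture whose
coefficients, standard errors and log-likelihood match R's
`survival::coxph` for both ties methods.

The stratified jump model regresses on stratum main-effect dummies plus
a within-stratum jump term for each stratum from 16–20 upward (a
10-point rise cannot land below MELD 16). Strata without both jump and
non-jump events are reported as NA; event-free strata are folded into
the reference level rather than given a weakly identified dummy.

Harrell's C uses counting-process at-risk semantics: at each event time
the event interval's risk score is compared with the scores of all other
registrants' intervals covering that time (tied event times are not
comparable; tied scores count ½). A registrant-level mode collapses each
registrant to (outcome time, first-interval score). The standard error
treats per-event concordance fractions as independent contributions — a
rough clustering approximation, reported for orientation only.

## Composite scores

Equating the linear predictor of a MELD-only dropout model (coefficient
b_M) with a joint model (b'_M, b_J, optionally interaction b_I) gives

    MELD_new = (b'_M / b_M) · MELD + (b_J + b_I · MELD) / b_M · I(jump).

Without an interaction the bonus is flat; rounding half-up yields the
"+2 points" rule from the canonical coefficients (0.178; 0.171; 0.386 →
slope 0.96, bonus 2.17 → +2). With a negative interaction the bonus
declines in MELD and is tabulated per MELD level (16–40), merged into
ranges. Choices: round-half-up for determinism; negative computed
bonuses clamped at 0 (deterioration never lowers priority); the applied
composite is capped at 40 to stay on the allocation scale. Exact
reproduction of any published points table is not asserted — such tables
derive from unrounded coefficients that are not recoverable from printed
precision — but the equated table under the pre-policy scenario lands
within a point of the published shape (7 at MELD 16 declining to 0 at
the top of the scale).

## Landmark calibration

For each MELD level the landmark cohort holds every registrant at the
first record where capped MELD *equals* the level (a first-crossing
variant is available), with the clock restarted and jump status frozen
at the landmark record. Observed dropout and transplant are estimated by
the Aalen–Johansen estimator,

    CIF_k(t) = Σ_{t_j ≤ t} S(t_j−) · d_kj / n_j,

with S the all-cause Kaplan–Meier; the pointwise 95 % bands use the
standard delta-method (Klein–Moeschberger) variance with a log
transform. (Point estimates match R `cmprsk::cuminc` exactly; the
variance differs from Gray's estimator in the third decimal.)

Predicted absolute dropout risk combines both causes' Breslow baselines
in the discrete product-limit form S(t−|x) = Π (1 − dΛ_d − dΛ_t), so a
null (β = 0) model reproduces the pooled Aalen–Johansen curve exactly —
a degeneracy asserted in tests. Prediction models are cause-specific
Cox fits on the pooled landmark rows with the landmark MELD as the
single covariate; the three compared scores evaluate that model at MELD,
MELD + 2, and MELD + points(MELD). Horizons are 30/90/180 days ("one,
three, six months" without calendar arithmetic). The summary discrepancy
is the mean absolute observed-minus-predicted dropout over grid cells
with at least 8 jump members. Plots smooth observed series with a
centred running mean (width 3 levels, display only), mirroring how such
calibration figures are usually drawn.

## Problem sizes and runtimes

Chosen so the full suite and the acceptance script each run comfortably
on one CPU: parameter recovery uses 20 replicates of n = 5,000
registrants (~1 min); the two calibration scenarios n = 12,000 (~30 s
each); the oracle sweep 10,000 registrants (~2 s). The acceptance script
repeats the main computations at the same scales (~2 min total).

## Known limitations

* The generator's hazards are exponential between visits; real waitlist
  hazards are neither piecewise-constant nor Markov in (MELD, jump).
* Jump persistence is a single global timer, not a frailty distribution.
* The C-index for time-varying covariates has no universally agreed
  definition; the record-level convention here matches the counting-
  process concordance of the R `survival` package in spirit but was not
  verified against it.
* Landmark prediction models are refit on pooled landmark rows rather
  than transported from the time-on-list fits; transporting baselines
  across time scales would require additional assumptions.
* No Fine–Gray subdistribution models and no post-transplant mortality.
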