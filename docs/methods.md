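# Methods

`crccal` couples a microsimulation model of colorectal-cancer natural
history to a likelihood-free calibration engine, and adds the
machinery needed to *recalibrate* an already-calibrated model when new
evidence arrives. This note records the model, the algorithmic and
numerical choices, and what the synthetic test bed does and does not
establish.

## The natural-history model

Each simulated person (agent) is followed in continuous time from age
20 to at most age 100 through four components of the
adenoma–carcinoma sequence.

**Adenoma risk.** Adenomas arise from a non-homogeneous Poisson
process with log-intensity

    ln ψ_i(a) = α0_i + α1·female_i
              + min(a−20, 30)·α20 + 1(a≥50)·min(a−50, 10)·α50
              + 1(a≥60)·min(a−60, 10)·α60 + 1(a≥70)·(a−70)·α70

for age `a ≥ 20` and ψ = 0 before 20. The person-level intercept is
`α0_i ~ N(A, σ_α)`, with `σ_α` interpreted as a standard deviation.
Because every age term is capped at its knot, exactly one slope is
active per age segment, and the intensity is piecewise log-linear —
its integral has a closed form and event ages can be drawn exactly.

**Adenoma growth.** Each adenoma draws a hypothetical time to reach
10 mm from a Fréchet distribution, `F(t) = exp(−(t/β₂)^(−β₁))`, with
separate (shape, scale) pairs for colon and rectum. That time anchors
a Richards growth curve

    d(t) = d∞ [1 + ((d0/d∞)^{1/p} − 1) e^{−λt}]^p

running from `d0 = 1` mm to the asymptote `d∞ = 50` mm; the rate `λ`
is solved in closed form so that `d(t₁₀ₘₘ) = 10`.

**Transition to preclinical cancer.** The lesion size at malignant
transition is log-normal; the mean of the underlying normal depends on
sex, site, their interaction, and age at initiation expressed in
decades centred at 50 (`(init_age − 50)/10`), with standard deviation
`σ_γ`. An adenoma transitions if and only if its growth curve reaches
that size within the horizon, which makes transition probability
increase with attained size.

**Sojourn time.** The preclinical-to-clinical interval is Weibull with
survival `exp(−(t/λ₁)^{λ₂})` in the colon. For rectal cancers we use
the *accelerated-scale* convention — scale `λ₁·e^{λ₃}`, same shape —
so the closed-form mean sojourn time is `λ₁ Γ(1+1/λ₂)` (colon) and
`λ₁ e^{λ₃} Γ(1+1/λ₂)` (rectum). A Weibull proportional-hazards
reading of the location effect would instead give mean
`λ₁ h^{−1/λ₂} Γ(1+1/λ₂)`; the scale convention is adopted because it
is the one consistent with the printed mean-sojourn-time formulas this
package reproduces.

**Other-cause mortality** comes from a synthetic piecewise-constant
hazard life table (rising hazards with age, configurable), which
preserves the censoring structure without external data. Death before
clinical presentation censors a cancer; clinical detection ends the
natural-history trajectory (stage at detection and post-diagnosis
survival are out of scope).

Of the parameters, 22 are calibrated (`A, σ_α, α1, α20, α50, α60, α70,
β₁c, β₂c, β₁r, β₂r, p, γ0..γ5, σ_γ, λ₁, λ₂, λ₃`); `d0` and `d∞` are
fixed inputs. With only two anatomical sites modelled, new adenomas
are rectal with a configurable probability (default 0.25) — a
deliberately simple stand-in for full colon anatomy.

### Sampling schemes

The per-agent reference path (`natural_history.simulate_agent`) draws
adenoma initiations by thinning with a per-segment constant majorant —
the log-intensity is linear on each segment, so the segment maximum
sits at an endpoint and the scheme is exact. The batch path
(`population.simulate_population`) uses the equivalent exact
decomposition: a Poisson count with the closed-form mean
`∫ψ`, then initiation ages i.i.d. with density ∝ ψ, inverted in
closed form within segments. Both are exact samplers of the same
process; a test holds their output distributions together. Each agent
owns a generator seeded by `SeedSequence([master_seed, agent_id])`, so
single-agent histories are reproducible independent of batch order.

A third implementation, `_fastsim`, is a numba-compiled scalar-loop
version of the batch path used on the calibration hot path (roughly
2× the throughput of the numpy path and, more importantly, cheap
staged evaluation; see below). It draws from numba's own generator, so
its streams differ from the numpy path; a distributional-agreement
test ties the two backends together. Study populations are simulated
only to just past the last age their statistics observe (registry 81,
colonoscopy study 75, sigmoidoscopy trial 64): later events cannot
enter the statistics, so the truncation is exact.

## Screening

Colonoscopy sensitivity for adenomas is a monotone piecewise-linear
function of lesion diameter through the anchors (5 mm, 0.81),
(10 mm, 0.92), (15 mm, 0.98), extended to 0.70 at the 1 mm detection
floor and 1.0 from 20 mm. Preclinical-cancer sensitivity is the
maximum of 0.95 and the size-based value, hence exactly 0.95 up to
12 mm. Flexible sigmoidoscopy reaches all rectal lesions and a
configurable fraction (default 0.4) of colonic lesions — a distal-colon
stand-in given the two-site anatomy. The whole model serialises to
YAML so re-specifying a fixed input (e.g. lower small-adenoma
sensitivity) is a configuration change.

`screening.simulate_screen` draws per-lesion Bernoulli detection
outcomes. The *target statistics*, however, use the conditional
expectation of detection given the lesion roster (per-lesion detection
probabilities, per-agent probability of at least one detection):
Rao–Blackwellization removes the detection-draw noise from the
statistics while leaving their estimands unchanged, which matters
because acceptance bands for precise targets are narrow.

## Calibration targets

A target couples a published summary statistic (its observed value and
sample size) to two accept bands: a *final* band — the Wilson score
interval at the study's own sample size — and an *initial* band
widened about the observed value by a factor (default 10) and
truncated to the statistic's natural range. Rates per 100,000 and
per-1,000 yields are handled on the proportion scale and rescaled.
Size categories ≤5 mm / 6–9 mm / ≥10 mm are operationalized as
half-open bins [1, 5.5), [5.5, 9.5), [9.5, ∞) mm.

Simulation noise must not swamp an accept band: each target can be
checked against its study's population size
(`targets.check_mc_precision`), which flags (or refuses) targets whose
binomial Monte Carlo standard error exceeds a fraction (default 20%)
of the final half-width. The synthetic scenario runs this check in
warning mode and sizes the sigmoidoscopy-trial population accordingly
(below).

## The calibration engine

The engine is an incremental-mixture approximate Bayesian computation
(ABC) sampler in the adaptive-importance-sampling family:

1. Draw `n_init` parameter vectors from the prior (independent
   truncated-normal or uniform margins); keep those whose simulated
   statistics fall inside every initial band.
2. Iterate: add multivariate-normal proposal components centred at
   high-weight accepted draws; sample a batch from the defensive
   mixture (weight 0.1 on the prior, the rest split equally across
   components); simulate; accept draws inside every current band;
   shrink each band one step toward its final band; reweight.
3. Stop when the effective sample size `ESS = (Σw)²/Σw²` over draws
   inside every *final* band reaches the target (5,000 at full scale;
   200 in the desk-scale tests), or flag the state unconverged at the
   iteration cap.

Importance weights are `prior(θ)/q_eff(θ)` for in-band draws and zero
otherwise. Because the pooled draws were generated by *different*
proposals across iterations, `q_eff` is the stage-size-weighted
average of every proposal that actually generated draws (the balance
heuristic / deterministic-multiple-mixture estimator), not the latest
mixture alone — weighting by the latest mixture alone is biased, which
an analytically solvable toy problem in the test suite demonstrates.

Component construction: centers are the highest-weight accepted draws
not yet used as centers, with draws inside the final bands ranked
first; the covariance is the sample covariance of the nearest accepted
draws (coordinate-standardized distance, neighbourhood of
`max(2k+2, 20)` draws), regularized by adding `1e−8 × trace` to the
diagonal, with a diagonal fallback spanning a tenth of the prior range
for degenerate neighbourhoods. Ties break by draw id, so runs are
deterministic given the seed. Interval shrinking interpolates each
endpoint toward the final band by a configurable step (default 0.5;
1.0 jumps straight to final) and skips — with a log record — any step
that would leave fewer than a configured minimum of draws (default 50)
inside all bands.

Simulators may expose `stages`: an ordered partition of the statistics
into groups with their own evaluation functions. The engine evaluates
stages in order and abandons a draw as soon as any computed statistic
falls outside its accept band; acceptance is a conjunction, so this
early veto is exact and saves the cost of expensive statistics for
doomed draws. Simulator calls within a batch are order-independent
(each draw's seed is `SeedSequence([master_seed, draw_id])`) and may
be mapped in parallel through the `map_fn` hook; results are identical
to serial execution.

### Sequential recalibration (warm start)

By Bayes' rule, `p(θ|y,z) ∝ p(θ|y)·p(z|θ,y)`: a posterior calibrated
to targets `y` is a better starting population for `{y,z}` than the
prior. `warm_start_recalibration` re-simulates every stored draw under
its stored seed — reproducing the `y` statistics bit-for-bit while
scoring the new `z` statistics — re-applies acceptance with `z` at its
initial bands, keeps the stored mixture components, and resumes the
ordinary loop (iteration counter continuing) until the ESS target is
met on the combined set. If no stored draw satisfies `z`'s initial
bands the warm start has degenerated and the engine says so; the
remedy is wider initial bands or a fresh calibration. How the original
full-scale study scored new targets for previously accepted draws is
not documented; seed-reuse re-simulation is this package's mechanism.

State (bands, draws with seeds, mixture components, sampling-stage
record, config, counters) serialises to JSON plus a draws CSV with
17-significant-digit floats, and a run resumes from file bit-for-bit.

## The synthetic test bed

No real registry or trial data ship with the package. A `Scenario`
fixes a ground truth θ*, simulates the model there on populations ten
times the per-draw size, and perturbs each statistic by binomial noise
at a stated "published" sample size to produce observed targets with
Wilson bands — so the targets have the statistical structure of real
calibration data while the truth is known.

The default scenario frees the three sojourn-time parameters
(λ₁, λ₂, λ₃), fixing the rest at θ*. Ground-truth sojourn values
(3.77, 2.38, 0.87) sit near published recalibrated means so posterior
scales are comparable to printed results without claiming to reproduce
them; the remaining components were chosen once to give realistic
epidemiology (adenoma prevalence ≈ 0.20–0.28 at colonoscopy ages,
clinical incidence ≈ 100–220 per 100,000 at ages 55–80, about 30
preclinical cancers per 1,000 large detected lesions, screen-detection
rates of a few per thousand with a male excess). The original target
set `y` holds eight targets across the usual kinds (incidence by sex,
prevalence by sex, two size-bin percentages, a per-1,000 yield, and
one imprecise overall screen-detection rate from a 1,994-person
study); the new set `z` holds the two precise sex-specific
screen-detection rates with trial sample sizes 20,519 (men) and
20,155 (women). The imprecise screen target's final band is
deliberately widened to three Wilson half-widths so the precise trial
bands nest strictly inside it — adding `z` then genuinely tightens the
constraint, which is the premise of the recalibration experiment.

Study populations per parameter draw: 2,000 agents each for the
registry and colonoscopy studies and 10,000 for the sigmoidoscopy
trial. The trial population is larger for the same reason the
MC-precision check exists: its targets carry half-widths near 1/1,000,
and with 2,000 agents simulation noise would dominate the accept
decision (measured joint acceptance at the truth ≈ 0.006, versus
≈ 0.05 with 10,000). Even at 10,000 agents the trial targets remain
noisier than the 20% rule would demand — the check runs in warn mode —
so the desk-scale ABC posterior is somewhat widened by simulation
noise relative to an ideal run; both experiment arms face the same
noise, so the sequential-vs-scratch comparison is unaffected.

Desk-scale engine configuration used by the tests: 1,000 prior draws,
5 components × 50 draws per iteration, shrink step 0.8, minimum 30
draws retained, ESS target 200, at most 80 iterations. A full two-arm
replicate (original calibration, warm start, scratch calibration)
takes roughly one minute on one CPU.

**What passing tests show — and don't.** The synthetic bed
demonstrates that the engine recovers known parameters from targets
with realistic uncertainty structure, that warm-start and scratch
recalibration agree, and that the warm start is cheaper. It does not
reproduce full-scale published calibrations: real registry inputs,
40-target sets, ESS 5,000 and cluster-scale budgets are out of scope,
and real data carry secular trends, age-distribution detail and
between-study heterogeneity that the generator does not emulate.

## Numerical details

- Weighted quantiles (credible intervals) invert the right-continuous
  weighted empirical CDF; under equal weights this reduces to the
  usual inverse-empirical-CDF order statistic.
- Density-based comparison metrics (area overlap, Hellinger) use a
  Gaussian KDE with Silverman bandwidth `1.06·σ·n_eff^{−1/5}` on a
  512-point grid spanning the pooled range ± 3 bandwidths; weights are
  used by default, an unweighted mode is available. Self-comparisons
  land within ~0.02 of their ideal values at these settings.
- The credible-interval overlap score for intervals (L₁,U₁), (L₂,U₂)
  with intersection (L_I,U_I) is
  `0.5(U_I−L_I)/(U₁−L₁) + 0.5(U_I−L_I)/(U₂−L₂)`, zero when disjoint.
- Standardized mean difference is reported as an absolute value,
  standardized by the *reference* (first) sample's posterior SD.
- Mean-sojourn-time posteriors transform each draw through the closed
  form and then average; the transform of the posterior mean is not
  the mean of the transformed draws (Jensen), and a test checks the
  gap's direction.
- Degenerate inputs signal: zero-variance samples for KDE metrics,
  zero reference SD for SMD, zero-width intervals for CI overlap,
  empty strata or zero detected lesions for target simulation.

## Known limitations

- Two anatomical sites with a fixed rectal probability; no serrated
  pathway, no lesion-level anatomy beyond colon/rectum.
- One-time screens only; detected adenomas are removed and no
  surveillance or repeat screening is modelled; no test specificity.
- Stage/size at clinical detection and post-diagnosis survival are not
  modelled; the life table is synthetic.
- The engine's proposal components are Gaussian; heavy-tailed target
  regions rely on the defensive prior mass.
- Warm starts assume the new targets supplement (never contradict or
  replace) the original set; removal or replacement of targets is out
  of scope.
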