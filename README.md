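# crccal

Microsimulation of colorectal-cancer natural history with
likelihood-free (ABC) calibration and **sequential recalibration** —
updating an already-calibrated model when new evidence arrives,
without starting over.

Cancer-policy microsimulation models follow individual people through
the adenoma–carcinoma sequence: benign adenomas arise, grow, may turn
into preclinical (asymptomatic) cancer, and surface clinically after a
*sojourn time*. Model parameters cannot be estimated directly — they
are tuned so that simulated summary statistics (registry incidence,
adenoma prevalence at colonoscopy, screen-detection rates, …) land
inside tolerance bands around published values. That calibration is
expensive, and it has to be redone whenever better evidence appears.
`crccal` is for methodologists and modellers who want a working,
desk-scale implementation of that whole loop: the natural-history
simulator, the incremental-mixture ABC engine, the warm-start
recalibration step, and the metrics used to quantify how far a new
posterior moved.

## The model and the method

Four components describe each agent's history (ages in years,
diameters in mm):

1. **Adenoma risk** — a non-homogeneous Poisson process whose
   log-intensity is piecewise linear in age with knots at 50, 60, 70
   (zero risk before 20), a normal person-level intercept
   `α₀ᵢ ~ N(A, σ_α)` and a female effect.
2. **Growth** — each adenoma's time to reach 10 mm is Fréchet
   (`F(t) = exp(−(t/β₂)^{−β₁})`, site-specific), anchoring a Richards
   curve `d(t) = d∞[1 + ((d₀/d∞)^{1/p} − 1)e^{−λt}]^p` from 1 to 50 mm.
3. **Transition** — lesion size at malignant transition is log-normal
   with mean depending on sex, site and age at initiation.
4. **Sojourn time** — Weibull, `S(t) = exp(−(t/λ₁)^{λ₂})` in the
   colon, scale multiplied by `e^{λ₃}` in the rectum, so mean sojourn
   time is `λ₁Γ(1 + 1/λ₂)` and `λ₁e^{λ₃}Γ(1 + 1/λ₂)`.

Calibration is incremental-mixture ABC: draw parameters from the
prior, keep draws whose simulated statistics fall inside wide initial
tolerance bands, then iteratively add Gaussian proposal components at
high-weight draws, shrink the bands toward their final (Wilson-score)
widths, and importance-reweight until the effective sample size at the
final bands reaches its target. Because `p(θ|y,z) ∝ p(θ|y)·p(z|θ,y)`,
a converged run for targets `y` warm-starts the run for `{y,z}`: stored
draws are re-scored against the new targets (re-simulating under
stored seeds), the proposal mixture is kept, and the same loop
resumes. Posterior shifts are quantified by 95% credible-interval
overlap, kernel-density area overlap, standardized mean difference and
Hellinger distance.

No external data are required: a synthetic-scenario module generates
"observed" targets from a known ground truth with realistic binomial
noise at stated study sample sizes.

## Worked example

`examples/03_calibrate_and_recalibrate.py` calibrates the three
sojourn-time parameters (truth λ₁ = 3.77, λ₂ = 2.38, λ₃ = 0.87) to
eight synthetic targets, then warm-starts with two precise
sex-specific screen-detection targets, and compares against a
from-scratch calibration to the combined set:

```
truth: lambda1=3.77, lambda2=2.38, lambda3=0.87
sequential posterior (converged=True, ESS=208):
  lambda1: 95% CI (2.87, 7.79)
  lambda2: 95% CI (0.68, 4.74)
  lambda3: 95% CI (-0.92, 1.40)
  colon MST 5.15 (2.62, 7.83); rectum MST 6.64 (2.67, 13.19)
scratch posterior (converged=True, ESS=205):
  lambda1: 95% CI (2.11, 7.57)
  ...
sequential vs scratch agreement (1 = identical posteriors):
parameter  ci_overlap  area_overlap   smd  hellinger
  lambda1       0.908         0.915 0.272      0.111
  lambda2       0.985         0.882 0.091      0.101
  lambda3       0.879         0.889 0.317      0.131

simulator calls: warm start used 2720 after the restart vs 4127 for
scratch
```

Every true parameter sits inside both 95% intervals; the two
recalibration routes agree (overlap ≈ 0.9, Hellinger ≈ 0.1) while the
warm start needed far fewer simulator calls — the point of sequential
recalibration. MST lines are posterior summaries of the mean sojourn
time, computed per draw through the closed forms.

The other examples are smaller: `01` prints one agent's event history,
`02` the sensitivity curve (0.81 / 0.92 / 0.98 at 5 / 10 / 15 mm;
preclinical floor 0.95) and a simulated one-time sigmoidoscopy trial,
`04` the comparison metrics on published credible intervals.

A thin CLI wraps the same library functions:

```sh
crccal make-fixtures --seed 1 --out fixtures/
crccal calibrate --prior fixtures/prior.yaml --targets fixtures/targets_y.csv \
       --seed 1 --out state.json
crccal recalibrate --resume-from state.json --new-targets fixtures/targets_z.csv \
       --out state2.json
crccal compare --run-a state.json.draws.csv --run-b state2.json.draws.csv \
       --out report.csv
```

## Layout

- `src/crccal/natural_history.py`, `population.py`, `_fastsim.py` —
  the disease model (per-agent reference path, vectorized batch path,
  compiled hot path)
- `src/crccal/screening.py`, `targets.py` — test sensitivity, target
  simulation, tolerance intervals
- `src/crccal/priors.py`, `config.py`, `imabc.py` — the calibration
  engine and its resumable state
- `src/crccal/posterior_compare.py` — CI overlap, area overlap, SMD,
  Hellinger, MST posteriors
- `src/crccal/synthetic_study.py` — ground-truth scenarios and the
  two-arm (sequential vs scratch) experiment
- `docs/methods.md` — model, algorithm and design notes
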