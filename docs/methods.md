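# Methods

## Model

The segmentation clock is modelled as delayed transcriptional
autorepression with two state variables, mRNA `M(t)` and protein `P(t)`:

```
dM/dt = α_m h(P(t − τ_m)),   h(P) = 1 / (1 + (P/P₀)ⁿ)   − μ_m M
dP/dt = α_p M(t − τ_p) − μ_p P
```

Assumptions: deterministic mass-action kinetics with first-order decay; a
single repressor species acting through a Hill function; all of the
feedback lag lumped into two discrete delays, `τ_m` (transcription +
splicing/export, acting on the repressive input to transcription) and
`τ_p` (translation, acting on protein production). A change of variables
(`M` shifted by `τ_p`) turns this into a single-delay system, so only the
loop total `τ = τ_m + τ_p` affects the dynamics; the split is nevertheless
carried explicitly because gene-architecture manipulations address
specific components.

Out of scope by design: stochastic kinetics, cell–cell (Notch) coupling and
spatial wave propagation across the PSM, and parameter inference from
experimental data.

## Parameters

| symbol | field | default | units | meaning |
|---|---|---|---|---|
| α_m | `mrna_synthesis_max` | 0.032556 | conc·min⁻¹ | maximal transcription rate |
| μ_m | `mrna_degradation` | 0.126377 | min⁻¹ | mRNA decay (t½ ≈ 5.5 min) |
| α_p | `protein_synthesis` | 1.0 | min⁻¹ | translation rate per mRNA |
| μ_p | `protein_degradation` | 0.1 | min⁻¹ | protein decay (t½ ≈ 6.9 min) |
| P₀ | `repression_threshold` | 0.016278 | conc | half-maximal repression |
| n | `hill_coefficient` | 1.6625 | — | cooperativity |
| τ | `delay.total_min` | 39.45 | min | 2.55 transcription + 33.91 processing + 3.0 translation |

Concentrations are arbitrary units scaled so the wild-type protein peak is
exactly 1 (the scaling `(M, P, P₀, α_m) → (cM, cP, cP₀, cα_m)` is an exact
symmetry of the equations, so this normalization changes no dynamical
property).

### Calibration

The defaults are **calibrated stand-ins, not measured rates**. They are
produced by `hes7clock.calibration.calibrate_wild_type()`, a deterministic
coordinate search on `(ln μ_m, ln μ_p, n)` with shrinking steps. For each
candidate shape the baseline delay `τ₀` is solved by bisection so the
period is 120 min (the mouse clock), and the candidate is scored by the
relative mismatch of two delay-response targets: +2.1 min of
transcriptional delay should lengthen the period by 4.9 min, and +9 min by
20.2 min (the model predictions for a 10 kb insert at the fast and slow
polymerase velocity presets). The frozen result (objective 5.4 × 10⁻⁵,
35 evaluations) reproduces 120.00 min / +4.88 min / +20.32 min under the
package's default numerics. Every candidate is evaluated with the same
integrator and period estimator used downstream, so the calibration is
consistent with all reported quantities by construction.

The calibrated decay rates imply half-lives of ~5.5 min (mRNA) and
~6.9 min (protein). Measured Hes7 protein stability elsewhere in the
literature is slower (~20 min half-life); the calibration trades literal
rate constants for the delay-response behaviour the package exists to
reproduce. Conclusions that hinge on absolute decay rates should not be
drawn from these defaults.

The delay split follows the field's budget: transcribing the 2.8 kb unit
at the slow 1.1 kb/min preset (≈2.55 min), a small 3-min translation term,
and the remainder (≈33.9 min) assigned to splicing/export, which is
believed to dominate the intronic delay. Because only the total matters
dynamically, this split affects bookkeeping (which component an insert or
deletion modifies), not trajectories.

## Numerics

* **Integrator** — method of steps with classical fixed-step RK4,
  `dt = 0.05` min by default. Delayed values are read from the stored
  solution grid by linear interpolation; because the delayed stage times
  sit at a fixed real offset from the step index, interpolation weights
  are precomputed once per run. `dt` must be ≤ τ/10 (and no larger than
  any positive delay component) so stage lookups never leave computed
  history. Halving `dt` changes the estimated period by well under 0.1%.
* **History** — constant `(M₀, P₀) = (0, 0)` for `t ≤ 0` by default,
  configurable.
* **Non-negativity** — the vector field is non-negative on the boundary,
  so negative states can only arise from discretization error; undershoots
  smaller than 10⁻¹² are clipped to 0, anything larger raises an
  integration-accuracy error rather than being silently repaired.
* **Fixed point** — `P*` solves a monotone scalar equation by Brent's
  method at machine tolerance (residuals < 10⁻¹⁰ relative, tested);
  delays do not move the fixed point. Zero synthesis rates (transcription
  or translation switched off) are handled as exact special cases.
* **Critical delay** — from the linearization, the Hopf crossing
  frequency is `ω² = [−(μ_m² + μ_p²) + √((μ_m² − μ_p²)² + 4K²)]/2` with
  gain `K = −α_m α_p h′(P*)`, and
  `τ_c = [π − atan(ω/μ_m) − atan(ω/μ_p)]/ω`; when `K ≤ μ_m μ_p` no finite
  delay destabilizes the fixed point and `inf` is returned. A numerical
  τ-scan of the classifier agrees with `τ_c` within one 0.5-min grid step
  (tested at 5% tolerance).

## Oscillation metrics

* **Peaks** — local maxima with prominence ≥ 5% of the post-burn-in range
  (`prominence_fraction = 0.05`), refined to sub-grid accuracy by a
  three-point parabola. Burn-in default 360 min = three nominal periods.
* **Period** — mean inter-peak interval (default), or an autocorrelation
  estimate: every ACF echo peak in the first half of the lag range is
  located, and the period is the slope of echo lag against echo index.
  (Finite-window edge terms shift each echo by a nearly constant offset,
  which the intercept absorbs; a single-echo readout would carry that
  offset as bias.) The two estimators agree within one grid step on clean
  signals. Insufficient cycles yield `nan` markers with diagnostics, not
  exceptions, so parameter scans cross regime boundaries cleanly.
* **Damping ratio** — geometric mean of successive peak-to-trough
  excursions, each peak measured against the mean of its flanking troughs.
  Excursions (not absolute peak heights) keep the ratio meaningful when a
  trajectory decays toward a non-zero fixed point. The same excursions
  provide the amplitude.
* **Classification** — `arrested` if fewer than `min_peaks = 4` peaks
  survive burn-in and prominence filtering; `sustained` if the damping
  ratio lies in `[0.95, 1.05]` (ratios above the band are flagged
  "growing" but classified sustained — a bounded system is converging to
  its limit cycle); `damped` below the band. The experimental literature
  gives no quantitative damping criterion, so these thresholds are package
  conventions, exposed in configuration.

## Scenarios

* **Knock-in** (`knockin-5k/10k/20k`) — adds insert-length / velocity
  minutes to the transcription delay; both published polymerase velocity
  presets (1.1 and 4.8 kb/min) are carried and neither is privileged.
* **3′UTR loss** (`utr-loss`) — the measured 30% mRNA reduction is applied
  as reduced effective synthesis (`α_m × 0.7`); a stability-loss
  interpretation (raising μ_m) would change the clock's kinetics as well
  as its level and is not the default. Translation impairment is a second,
  independent scale on `α_p`; since no measured value exists, "severe" is
  explored by scan — under the default calibration the sustained/lost
  boundary sits near `translation_scale ≈ 0.1`, and full arrest with
  uniformly elevated mRNA (the observed in situ phenotype) near 0.01.
* **Intron deletion** (`intron-del-5`, `intron-del-19`) — removes minutes
  from the mRNA-side delay (processing first, then transcription). Under
  the default calibration the −19 min preset lands below the critical
  delay (20.45 < 21.38 min: oscillation lost) and −5 min remains sustained
  with a shorter period, reproducing the severe/mild dichotomy.

## Synthetic data

The generators exist so every estimator is testable without any
experimental download; all are pure functions of their inputs and a seed.

* **Noisy traces** — multiplicative (or additive) Gaussian noise per
  sample; truncation at zero is counted and logged. Multiplicative 5%
  noise is the default test condition; the period estimator recovers the
  generating period within 2% there.
* **Cell populations** — one deterministic trajectory, per-cell phase
  shifts drawn uniformly from `[0, phase_spread]`, plus noise. This is a
  deliberate caricature of the travelling PSM wave: it reproduces the
  graded-vs-uniform snapshot contrast between an oscillating and an
  arrested PSM, and nothing else — no coupling, no synchronization, no
  spatial mechanism. Passing tests say nothing about real tissue-level
  wave dynamics.
* **qPCR-style samples** — target and reference quantities with lognormal
  dispersion (σ = 0.1 by default; the reference experiment reports only
  mean ± s.e.m., so the dispersion is a package convention, recorded in
  outputs). Group sizes default to 14 wild-type vs 13 mutant. Analysis
  normalizes target by reference per sample, rescales to the wild-type
  mean, and reports means, standard errors and a Student's t-test — the
  mutant/wild-type ratio is recovered without bias beyond Monte-Carlo
  error.

## Problem sizes

Default runs integrate 1200–2400 min of model time at `dt = 0.05` min
(24–48 k steps, a fraction of a second each); the τ-scans and
noise-robustness checks in the test suite use tens of such runs. The full
calibration search (~500 integrations) runs in a few minutes and is not
part of the test suite; its frozen result is verified cheaply instead.

## Known limitations

* Parameter values are calibrated to the delay-response targets, not
  fitted to molecular measurements; absolute concentrations and decay
  rates are not interpretable.
* Single-cell, deterministic: no stochastic damping, no population
  desynchronization — the "damped" call refers to the deterministic
  envelope, which is only an analogy to damping observed across an embryo
  population.
* The linear-interpolation method-of-steps integrator is second-order
  accurate in the delayed terms despite the RK4 stepper; at the default
  `dt` this is far below metric tolerances but matters if `dt` is raised
  toward its τ/10 ceiling.
* Classification thresholds (prominence, sustained band, minimum peaks)
  are conventions; regime boundaries reported by scans move slightly if
  they are changed.
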