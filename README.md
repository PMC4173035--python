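# hes7clock

A delayed negative-feedback simulator of the mouse **Hes7 segmentation
clock**, for developmental biologists and modellers who want to ask: *what
happens to the ~2-hour somite clock when the architecture of the Hes7 gene
changes?*

In the presomitic mesoderm (PSM), the transcriptional repressor Hes7
inhibits its own promoter. Because transcription, splicing/export and
translation take time, the repression arrives late, and this **delayed
negative feedback** makes Hes7 expression oscillate with the ~120-min
period that paces somite formation. The package models this loop, converts
gene-architecture manipulations (intron knock-ins, intron deletions, 3′UTR
loss) into parameter changes, and quantifies the predicted phenotype:
period, amplitude, damping, and a sustained / damped / arrested call.

## Model

Two variables, mRNA `M(t)` and protein `P(t)`:

```
dM/dt = α_m · 1 / (1 + (P(t − τ_m)/P₀)ⁿ) − μ_m M
dP/dt = α_p · M(t − τ_p) − μ_p P
```

with Hill-type autorepression (threshold `P₀`, cooperativity `n`),
first-order decay (`μ_m`, `μ_p`), and a delay budget
`τ = τ_m + τ_p = transcription + processing + translation` (minutes).
The system is integrated by the method of steps with a fixed-step
fourth-order Runge–Kutta scheme (delayed values read from the stored grid
by linear interpolation). Closed-form companions: the unique fixed point
`(M*, P*)` and the Hopf critical delay from the characteristic equation
`(λ + μ_m)(λ + μ_p) = −K e^(−λτ)`.

Changing the gene changes the delay: inserting `L` kb of intron adds
`L / v` minutes of transcription time at polymerase velocity `v` (the
published range 1.1–4.8 kb/min is carried as two presets). The calibrated
wild-type parameter set oscillates at 120 min with a total delay of
39.45 min (critical delay 21.38 min); see `docs/methods.md` for how the
defaults were calibrated and what they do and do not represent.

## Worked example

```python
from hes7clock import WILD_TYPE, integrate, trajectory_metrics, knockin_scenario

traj = integrate(WILD_TYPE, t_end=1200.0, dt=0.05)      # 20 h, zero history
m = trajectory_metrics(traj, channel="mrna")            # 360 min burn-in
print(m.period_min, m.classification, m.damping_ratio)
# 120.01 sustained 0.999

r = knockin_scenario(insert_kb=10, speed_kb_per_min=4.8)
print(r.overrides["extra_delay_min"], r.period_change_min)
# 2.08 4.84
r = knockin_scenario(insert_kb=10, speed_kb_per_min=1.1)
print(r.overrides["extra_delay_min"], r.period_change_min)
# 9.09 20.52
```

Read: the wild-type clock is a sustained 120-min oscillator
(per-cycle amplitude ratio 0.999 ≈ 1). A 10 kb intron knock-in adds
2.1–9.1 min of transcription time depending on the polymerase velocity
assumed, and the model predicts the oscillation *stays sustained* while
the period lengthens by 4.8–20.5 min.

The same is available from the shell:

```sh
hes7clock delay --insert-kb 10 --speed 4.8        # delay budget as JSON
hes7clock scenario --name knockin-10k             # full scenario record
hes7clock scan --axis delay --grid 0,2.1,9        # period vs extra delay
hes7clock synth --kind qpcr --seed 1              # synthetic qPCR samples
```

Other presets: `intron-del-5` (mild delay reduction: sustained, faster),
`intron-del-19` (severe: oscillation lost), and `utr-loss` (reduced mRNA
output and impaired translation: damped/arrested with uniformly elevated
mRNA — the knock-in phenotype actually observed).

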