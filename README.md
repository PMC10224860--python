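# vhitkit

Simulation and analysis of **video head impulse test (vHIT)** recordings for
pre/post study designs, aimed at vestibular and motion-sickness researchers
who want a fully testable, reproducible desk-scale counterpart of a typical
vHIT study: synchronized head/eye angular-velocity traces at 220 Hz, the
standard per-impulse VOR gain metrics, and the 2×2 mixed-design inference
that compares participant groups across a pre/post intervention.

## What it computes

The vestibulo-ocular reflex (VOR) stabilizes gaze by counter-rotating the
eyes during head movement. In a vHIT session an examiner delivers brief,
passive, unpredictable yaw head impulses (≤ ±20°, accelerations up to
4700°/s²) while a combined tracker records head and eye velocity. The
pipeline computes, per impulse,

```
gain = − mean(eye velocity) / mean(head velocity)
```

over a fixed 10 ms window centered 60 ms after impulse onset (half-open
[55, 65) ms; the sign flip makes compensatory responses positive, so healthy
gain ≈ 1). Impulses are **valid** if peak head velocity exceeds 100°/s; a
direction needs at least five valid impulses, and its gain is the mean over
the **five fastest** valid impulses. Left/right gains are pooled and the
asymmetry index is

```
asymmetry = 100 · (gL − gR) / (gL + gR)   [%]
```

The statistics layer provides the 2×2 mixed repeated-measures ANOVA (within
factor: time pre/post; between factor: symptomatic vs asymptomatic), exact
for this design via the change-score decomposition and using Type III
conventions for unbalanced groups; BIC-approximate Bayes factors
`BF10 = exp((BIC₀ − BIC₁)/2)` with conventional evidence labels; Spearman
rank correlation (exact permutation p for n ≤ 8, t-approximation above); and
Monte-Carlo power / sample-size analysis for the time-by-group interaction
under correlated bivariate-normal pre/post measures.

Everything stochastic is seed-reproducible, including a full end-to-end run
(`vhit run`) whose outputs are byte-identical across reruns.

## Worked example

```python
from vhitkit import (TraceConfig, CohortConfig, PowerSpec, simulate_trace,
                     simulate_cohort, summarize_session, mixed_anova_2x2,
                     spearman, power_by_simulation)

# one synthetic session: 10 impulses per direction, true gain 1.04
s = summarize_session(simulate_trace(TraceConfig(seed=1)))
print(s.gain_left, s.gain_right, s.gain_pooled, s.asymmetry_abs)

# a 17-participant cohort (8 symptomatic, 9 asymptomatic) and its inference
cohort = simulate_cohort(CohortConfig(seed=1))
report = mixed_anova_2x2(cohort)
df = cohort.to_frame()
rho, p = spearman(df.mssq_short, df.nausea_max)

# interaction power at the design point, total N = 15
res = power_by_simulation(PowerSpec(n_reps=5000, seed=1), 15)
```

This prints (formatted):

```
left gain  : 1.041  (n valid = 10)
right gain : 1.044  (n valid = 10)
pooled gain: 1.043
asymmetry  : 0.12%
time         F(1,15) = 0.966, p = 0.341, BF10 = 0.41 (anecdotal evidence for the null)
group        F(1,15) = 0.192, p = 0.668, BF10 = 0.27 (moderate evidence for the null)
interaction  F(1,15) = 0.119, p = 0.735, BF10 = 0.26 (moderate evidence for the null)
spearman rho = 0.73, p = 0.001
power at N=15: 0.993 (95% CI 0.991-0.995)
```

The recovered gains sit within noise of the configured true gain 1.04; the
default cohort has no built-in group-by-time effect, so all three F tests
are null and the Bayes factors lean toward the null, while the MSSQ score
and the nausea rating correlate positively by construction. The interaction
test is strongly overpowered at N = 15 under these design assumptions.

## Command line

```sh
vhit simulate trace  --seed 1 --out trace.csv        # + trace.truth.csv sidecar
vhit simulate cohort --seed 1 --out cohort.csv
vhit process --pre pre.csv --post post.csv --out metrics.csv
vhit analyze --cohort cohort.csv --out report/
vhit power --n-grid 8:40 --reps 5000 --seed 1 --out power.csv
vhit run --config examples/run_config.yaml --seed 1 --out out/
```

`vhit run` executes the whole chain (cohort → traces → pipeline → inference
→ power curve) and writes a manifest with checksums of every artifact.

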