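# Methods

This note documents the models, conventions and numerical choices behind
vhitkit, in the order data flows through the package.

## Head-impulse model

A head impulse is modeled as a raised-cosine angular-velocity pulse

```
v(t) = (p/2) · (1 − cos(2πt/T)),   0 ≤ t ≤ T,
```

with peak velocity `p` (°/s) and duration `T` (s), signed by direction
(positive = rightward yaw). The envelope was chosen because its constraints
have closed forms: peak acceleration `πp/T` and total displacement `pT/2`.
Accepted kinematics must satisfy `πp/T ≤ 4700 °/s²` and `pT/2 ≤ 20°`, the
physical envelope of a hand-delivered impulse; jointly these bound feasible
peaks at `p ≤ √(4700·40/π) ≈ 244 °/s`. The simulator's default peak range
(150–220 °/s at `T = 0.15 s`, i.e. accelerations 3100–4600 °/s²) fills most
of that envelope while staying above the 100 °/s validity cut.

Real impulses are asymmetric and followed by a small rebound; the
raised-cosine is symmetric and rebound-free. Nothing downstream depends on
pulse shape beyond the gain window, so this idealization mainly means the
detector is tested under cleaner conditions than clinical data provide.

## Trace synthesis

A session contains `n` impulses per direction in randomized order, separated
by ≥ 0.5 s of quiescence plus a uniform 0–0.5 s jitter (impulse timing is
unpredictable by design in a real session; the 0.5 s floor is this package's
choice). Onsets snap to the sample grid so recorded ground truth is exact.
The eye channel is

```
eye(t) = −g_dir · head(t − λ) + ε(t) + saccades,
```

with per-direction true gain `g_dir`, VOR latency `λ` (default 0 s — the
gain window applies no latency compensation, so a nonzero latency biases
recovered gains, which is faithful to how the fixed-window method behaves),
white noise `ε` of SD 5 °/s (typical video-oculography velocity noise), and
optional catch-up saccades: 30 ms raised-cosine transients of 30–80 °/s
placed 20–60 ms after impulse offset — after the gain window closes, so they
stress detection without biasing gains. Noise is applied to the eye channel
only; the head channel is the examiner-prescribed stimulus.

What the simulator does **not** emulate: pupil-tracking dropouts, blink
artifacts, goggle slippage, head-velocity measurement noise, overshoot in
the head trace, and anticipatory eye movements. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model, not
robustness to every clinical artifact.

## Cohort model

A cohort is built from four subgroups (susceptible × symptomatic). Defaults
describe a 17-participant cohort (2 + 6 symptomatic, 4 + 5 asymptomatic)
with subgroup-specific means/SDs for age, MSSQ-Short score and pre/post
gains. Each participant's (pre, post) gain pair is bivariate normal with the
subgroup moments and correlation ρ (default 0.7, the standard planning value
for repeated gain measures). MSSQ scores and nausea ratings share a
Gaussian-copula latent variable with weight 0.6 (default), chosen to give a
clearly positive but imperfect rank correlation; symptomatic nausea ratings
are integers mapped from the latent quantile into the subgroup's range
(≥ 1, capped at 10), asymptomatic ratings are 0 by definition of the group.

## Impulse detection

The detector flags a crossing of |head velocity| above 50 °/s, backtracks to
the last sample below 20 °/s within 0.1 s, then continues down the monotone
descent to the foot of the velocity rise; that sample is the onset. Events
within 0.5 s of the previous onset are suppressed. Peak velocity and
acceleration (finite differences) are measured on the excursion. Vendor
detection algorithms are proprietary; these thresholds guarantee every valid
impulse (> 100 °/s) is detectable, and on simulated data onsets are
sample-exact.

## Gain, validity, aggregation, asymmetry

* Gain window: half-open `[onset + 55 ms, onset + 65 ms)` on sample
  timestamps — 2–3 samples at 220 Hz. A fixed, documented convention; the
  half-open edge makes window membership unambiguous when a sample lands on
  the boundary. If |mean head| < 1 °/s in the window the ratio is degenerate
  and the impulse is invalidated.
* Validity: peak head velocity strictly greater than 100 °/s ("exceeds"
  read as strict; only relevant for peaks exactly at threshold).
* Direction gain: mean of the gains of the five fastest valid impulses,
  ties on peak velocity broken by earlier onset (a deterministic tie-break
  so reruns are identical).
* Pooled gain: unweighted mean of the two direction gains (default).
  A `pooling="all-impulses"` switch instead averages the five fastest of
  both directions together; the two differ only under unbalanced counts.
* Asymmetry: `100·(gL − gR)/(gL + gR)` percent; signed value kept for
  diagnostics, magnitude reported in summaries. Undefined (error) when the
  gain sum is non-positive.
* A direction with fewer than five valid impulses excludes the participant
  (error in strict mode, an `excluded` flag plus reason otherwise).

## Mixed 2×2 ANOVA

With two repeated measures the mixed design decomposes exactly: the group
effect is a one-way comparison of subject means `u = (pre + post)/2`, the
time effect and interaction are tests on change scores `d = post − pre`. All
effects are F(1, N−2). For unbalanced groups the package uses Type III
(unweighted marginal means) conventions: the time effect tests the
unweighted average of the two group mean changes. The interaction F equals
the squared pooled-variance two-sample t on `d` — an identity the test suite
verifies to 1e-8 and the power machinery exploits. Zero error variance
raises an error rather than returning NaN. Cross-checks: pingouin's mixed
ANOVA (balanced case, all effects; unbalanced, group + interaction) and
statsmodels' Type III OLS on change scores (unbalanced time/interaction).

## Bayes factors

`BF10 = exp((BIC_null − BIC_alt)/2)` per effect, computed from the effect's
F statistic via `BIC_null − BIC_alt = n·ln(1 + F·df1/df2) − df1·ln(n)` with
`n` the number of per-subject scores entering that effect's sub-model. This
is the unit-information-prior approximation, not the multivariate default
priors of dedicated Bayesian ANOVA software; values are comparable at the
evidence-band level (anecdotal/moderate/strong/…, standard cut-offs at 1, 3,
10, 30, 100 and their reciprocals), and are labeled accordingly.

## Spearman correlation

Midranks for ties, Pearson correlation on ranks. Two-sided p: exact
enumeration of all n! pairings for n ≤ 8; for larger n the t approximation
`t = ρ√((n−2)/(1−ρ²))` on n−2 df. The breakpoint sits where full enumeration
stays effectively instantaneous (8! = 40 320); typical cohort sizes (n ≳ 15)
are far into the t regime either way.

## Power and sample size

`power_by_simulation` draws replicate cohorts of correlated bivariate-normal
(pre, post) pairs — per-measure SD σ, correlation ρ, group-specific mean
changes — splits total N as evenly as possible (larger half symptomatic),
and counts interaction rejections at α, using the change-score t² identity;
the rejection proportion carries a 95% Wilson interval. Under the default
design assumptions (change 0.1 vs 0, σ = 0.05, ρ = 0.7) the change-score SD
is `σ√(2(1−ρ)) ≈ 0.039`, making the interaction test strongly overpowered at
N = 15. An analytic noncentral-F variant is provided with its convention
stated explicitly: `λ = f²·N·m/(1−ρ)` with m = 2 measures and Cohen's
f = (SD of interaction cell deviations)/σ (= 0.5 at the defaults), on
(1, N−2) df; simulation and analytic power agree to ~0.02. Published
sample-size calculations using other effect-size conventions can give
different minima for the same verbal assumptions, which is why the package
reports power at a given N rather than asserting a unique minimal N;
`minimal_n` performs the ascending search when the user wants one, with a
cap error if the target is unreachable.

Monte-Carlo sizes: 5 000 replicates for power estimates (SE ≤ 0.007),
10 000 for null-calibration checks (SE ≈ 0.002 at α = 0.05), 500 seeded
sessions for the noise-robustness rate — sizes at which the checked margins
are several Monte-Carlo SEs wide.

## Reproducibility

Every stochastic operation is a pure function of (config, seed). The
end-to-end runner derives per-stage child seeds with numpy's
`SeedSequence(entropy=seed, spawn_key=(stage, index…))`, so a stage can be
re-run in isolation. Trace CSVs are written with exact shortest-decimal
floats (lossless round-trip, needed to keep the 1e-9 timestamp-uniformity
contract after read-back); derived tables use 9 significant digits. Both are
deterministic, so identical (config, seed) reproduces every artifact byte
for byte, which the manifest's checksums record.

## Known limitations

* Horizontal (yaw) VOR only; no vertical canal or otolith testing.
* The head trace is prescribed, not biomechanically generated.
* The BIC Bayes factor is an approximation; do not compare its numeric
  value against software using multivariate Cauchy priors except at the
  evidence-band level.
* The fixed-window gain is biased when VOR latency is nonzero; this is a
  property of the method, preserved deliberately.
* Nausea is summarized as a single maximum score per participant; no
  per-minute symptom trajectory is modeled.
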