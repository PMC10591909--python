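# Methods

This note documents the statistical model behind `invivosyn`, the
parameters that matter, the numerical choices, and the limits of what the
simulation-based tests demonstrate.

## The efficacy metric (eGR)

A mouse's growth curve (t₀ < … < t_n, TV₀ … TV_n, volumes in mm³) is
reduced to one number: the rate constant of the exponential curve with the
same net log-scale area. Concretely,

    AUC_net = trapezoid(ln TV over days) − d · ln TV₀,      d = t_n − t₀
    eGR     = 2 · AUC_net / d²          (units 1/day)

The normalization follows from the defining requirement that an exact
exponential TV₀·e^{kt} yields eGR = k: its net log-area is k·d²/2. The
trapezoid rule is exact on log-linear segments, so eGR is also invariant
to sampling density on such curves, and invariant to rescaling all volumes
(only ln TV − ln TV₀ enters). No growth model is fitted; a curve that
shrinks then regrows contributes its *net* behavior.

Each mouse uses its **own duration d** — this is what lets uneven designs
(control euthanized early, responsive arms followed for weeks longer)
contribute all of their data, where single-day methods must stop at the
last common day. Curves with fewer than two measurements cannot support a
rate and are excluded with a warning (they stay visible in validation
reports). An optional `max_day` truncates every curve first, for studies
where all analyses should use data up to a fixed day (e.g. 21). Group eGR
is the unweighted mean over the group's analyzable mice; groups may be
unbalanced.

## Synergy models

With t as evaluation time (default **21 days**, configurable — three weeks
of treatment, chosen so CI lives on the scale familiar from cell-line
studies), relative survivals are S_g = exp(−(eGR_C − eGR_g)·t) for
g ∈ {A, B, AB}; values above 1 (growth acceleration) are legal.

* Bliss independence: expected combo survival S_A·S_B;
  CI = S_AB/(S_A·S_B) = exp(t·(eGR_C + eGR_AB − eGR_A − eGR_B)),
  SS = 100·(S_A·S_B − S_AB).
* HSA: expected survival min(S_A, S_B) (min is symmetric, no tie-break
  needed); CI = S_AB/min(S_A,S_B), SS = 100·(min(S_A,S_B) − S_AB).

CI < 1 ⇔ SS > 0 (synergy) holds algebraically for both models, and when
both single agents are effective (S_A, S_B ≤ 1) the Bliss expectation is
smaller, so HSA CI ≤ Bliss CI: Bliss is the stricter claim. CI and SS
magnitudes depend on t (and implicitly on the chosen doses); their sign
does not, which is why the P value is the better cross-study comparator.

## Bootstrap inference

Resampling unit is the **mouse** (whole curve), drawn with replacement
within its treatment group, each group to its original size — the strata
preserve the 4-group design and within-mouse correlation. Per-mouse eGR is
a deterministic function of the curve, so each bootstrap replicate's
pipeline reduces to re-averaging resampled per-mouse eGRs; the
implementation exploits this (the test suite asserts equivalence with
naively re-running the full pipeline per resample). Indices are drawn from
one seeded generator in the fixed group order C, A, B, AB, making runs
bit-reproducible.

Intervals are Efron's BCa: bias term z₀ = Φ⁻¹ of the fraction of bootstrap
values below the observed statistic (ties half-weighted), acceleration
a = Σ(θ̄−θᵢ)³ / (6·(Σ(θ̄−θᵢ)²)^{3/2}) from leave-one-mouse-out jackknife
values (each mouse removed within its own stratum; strata of size 1
contribute none). CI is processed on the log scale — its bootstrap
distribution is approximately log-normal and the additivity null is
log CI = 0 — and the interval is exponentiated back; SS is processed on
its natural percentage-point scale. Degenerate (zero-spread) bootstrap
distributions yield the flagged interval (v, v) and no P value; adjusted
quantile levels that fall outside (0,1) are clamped to the extreme order
statistics and flagged.

The **P value** is the smallest α for which the null value leaves the
(1−α) BCa interval, found by bisection, so P and the reported interval can
never disagree; it is floored at 1/n_boot (default n_boot = 1000).
Because log CI(t) = t · (rate contrast), changing the evaluation time
rescales the whole bootstrap distribution and its null together — the CI
P value is *exactly* invariant to t (bitwise, at fixed seed). The SS P
value is nearly but not exactly t-invariant (SS mixes two exponential
contrasts, so replicate ranks can shift with t).

Known small-sample property: with few mice per group the bootstrap
understates the sampling SD of a stratum mean by the factor
√((n−1)/n) and uses normal rather than t quantiles, so two-sided
rejection of the additivity null runs above nominal (~13% at α = 0.05
with n = 6). Directional synergy claims (P < α *and* SS > 0) run at
~6% — close to nominal — which is the quantity that matters for the
false-discovery behavior of a synergy screen. This is a property of
percentile-type stratified bootstrap at these sample sizes, not of the
implementation.

## Single-day baseline (gCI)

For comparison, the local Bliss CI at day x is
ln µ_A + ln µ_B − ln µ_C − ln µ_AB, where µ_g is the group mean of
per-mouse relative TV (TV_x/TV_first; per-mouse-then-average for
robustness to baseline spread), computable only when **all four groups**
have a mouse measured exactly at x (no interpolation). Treatment effects
δ_g = (µ_C − µ_g)/µ_C are reported alongside. gCI is the mean of local
values over computable days > 0 (day 0 is excluded: all relative TVs equal
1 there and the local CI is identically 0). Orientation is opposite to the
eGR-based CI: local CI > 0 means synergy. The baseline's documented
weakness — losing every day after the control group's euthanasia — is
reproduced by construction on simulated delayed-effect studies. Point
values only; no interval machinery is provided for gCI.

## The tumor-growth simulator

Exponential growth TV(t) = TV₀·e^{kt} with treatment as a rate offset:

| parameter | meaning | default |
|---|---|---|
| tv0_mean | mean initial TV (treatment starts at 100–300 mm³ in practice) | 200 mm³ |
| cv0 | between-animal CV of TV₀ (log-normal) | 0.20 |
| k_mean (or DT) | control growth rate; k = ln2/DT | ln2/7 ≈ 0.099/day |
| cvk | between-animal CV of k (normal, truncated > 0) | 0.03 |
| sigma | log-scale SD of multiplicative measurement error | 0.03 |
| tgi21 | per-arm day-21 tumor growth inhibition | scenario |
| t_ki | kick-in delay (control rate before, treated after) | 0 |
| p_rt, t_ir | resistant fraction and its emergence day (0 = intrinsic) | 0 |
| tv_max | euthanasia threshold (crossing measurement kept) | 3000 mm³ |
| t_obs, schedule | follow-up and measurement days | 21 d; 0,4,7,10,14,18,21 then +4/+3 alternating |

The TGI→rate map k_tr = k + ln(1−tgi21)/21 makes the noise-free day-21
relative-TV ratio exactly 1−tgi21 (TGI = 1 is a complete kill and not
representable by a finite rate). Resistance is a two-population mixture:
at t_ir a fraction p_rt of the current population reverts to the control
rate; t_ir = 0 reduces to the intrinsic-resistance mixture
p_rt·e^{kt} + (1−p_rt)·(treated curve). Distribution choices (log-normal
TV₀, truncated-normal rate, multiplicative log-normal error) keep volumes
positive and match the log-scale analysis; each is a swappable policy, not
a claim about mechanism.

**Noise calibration.** The between-animal and measurement noise defaults
(cvk = 0.03, sigma = 0.03) are calibrated so that the simulated
design-guidance properties reproduce the published behavior of this class
of method: strong Bliss synergy (combo TGI 0.8 over 0.5/0.4 singles)
detectable with 2 mice per group and saturating by 6; weak synergy (combo
TGI 0.75, the midpoint of the 0.7–0.8 bracket) requiring 8–10 mice; a low
false-synergy rate under exact additivity (combo TGI 0.7); power
increasing with doubling time and only weakly sensitive to the euthanasia
cutoff. These are optimistic relative to typical caliper data (measurement
CVs of 10–20% are common); with realistic noise the same strong-synergy
contrast needs far more animals. Passing power tests therefore
demonstrate the pipeline's behavior under the stated conditions, not that
2 mice suffice in a real study. cv0 = 0.2 is kept at a realistic level;
eGR's scale invariance makes starting-volume spread essentially irrelevant
to power.

## Power analysis

Power at a design point = fraction of `n_sim` independently simulated
studies (default 100) in which **synergy is detected**: P < α (default
0.05, Bliss SS statistic by default) *and* the observed effect is on the
synergy side (SS > 0). The directional condition matters: a delayed-onset
combination is transiently antagonism-signed under Bliss at short
follow-up (the immediate single-agent effect of drug B is expected of the
combo but hasn't kicked in), and regrowth scenarios drift toward
antagonism at long follow-up — counting such two-sided rejections as
"power to detect synergy" would be wrong. `direction="two_sided"` restores
plain rejection counting. Under an exactly additive combo, the same number
is the rate of false synergy claims.

Seeds form a hierarchy (master → grid point → replicate → separate
simulation and bootstrap streams), so every grid point and replicate is
individually reproducible and points are independent. Replicates whose
simulated study is structurally unanalyzable (extreme truncation) are
regenerated from the next substream and counted; degenerate-inference
replicates are counted and excluded from the denominator. Wilson 95%
binomial intervals accompany every power estimate.

Problem sizes used by the shipped checks: the acceptance script runs
100 simulations × 1000 bootstrap resamples per benchmark; the test suite's
calibration and trend checks use 50–200 simulations with 200 resamples
(scaled-down fast mode) and binomial tolerances sized accordingly.

## Known limitations

* The simulator is purely exponential with rate offsets — no Gompertz or
  logistic saturation, no dose–response/PK submodel, no body-weight or
  toxicity endpoints.
* Only Bliss and HSA nulls: single-dose 4-group designs cannot identify
  Loewe/ZIP/MuSyC-style models that need dose–response curves.
* Bootstrap inference is anticonservative two-sided at very small group
  sizes (see above); directional synergy claims are close to nominal.
* The delayed-effect Bliss contrast changes sign with follow-up length
  (antagonism-signed before the combination's kick-in benefit outweighs
  the expected immediate single-agent effect, crossing near T_obs ≈ 40
  under the benchmark settings); interpret CI direction at short
  follow-up with care.
* gCI baseline is point-value only, as a comparator.
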