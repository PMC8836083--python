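# Methods

This note records the model, its numerical treatment, and the design
choices made where the published description left the formulation open.

## Model structure and assumptions

The cell is a two-compartment (cytosol/ER), spatially homogeneous,
deterministic oscillator.  Four variables — cytosolic Ca²⁺ `c`, ER Ca²⁺
`c_e`, IP₃R gating `h`, IP₃ `p` — exchange Ca²⁺ through four fluxes
(IP₃R release, SERCA reuptake, leak + store-operated entry, plasma-
membrane extrusion).  The combination `c + c_e/γ` changes only through
the plasma-membrane terms `δ(J_in − J_pm)`; ER release and reuptake
conserve total cell Ca²⁺.  This identity is asserted to 1e−12 in the
test suite and is the model's basic bookkeeping invariant.

The model targets the oscillation *frequency* only.  Spike shape and
amplitude are outside its remit, as are spatial gradients, stochastic
channel gating, fluorescence-indicator kinetics, and any pharmacokinetics
of the two drugs (a dose is a constant during a simulation).

### IP₃R open probability

The printed open-probability expression in the source material is
typographically garbled; the reconstruction used here is the two-mode
gating scheme of the model family this model derives from:

    P_O = β / (β + k_β (β + α))
    β = B(p) m(c) h,   α = (1 − B(p)) (1 − m(c) h∞(c))
    m(c) = c⁴/(K_c⁴+c⁴),  h∞(c) = K_h⁴/(K_h⁴+c⁴),  B(p) = p²/(K_p²+p²)

Two readings were screened numerically before settling on this one:

* `A(p) = B(p) = p²/(K_p²+p²)` (both rates increasing in IP₃) admits
  **no oscillatory regime anywhere** in the admissible p_s range with the
  published kinetic constants;
* `A(p) = 1 − B(p)` (IP₃ suppresses inactivation) oscillates and
  reproduces the published control period with p_s ≈ 0.10 µM.

The alternative composition `P_O = β/((1+k_β)β + α)` is related to the
adopted one by reparameterization and gives indistinguishable drug
responses once p_s is recalibrated.

The 0/0 ambiguity at `α = β = 0` (no IP₃) is resolved to a closed
channel, the continuous p → 0 limit.

### Drug factors and the sign of the crosstalk term

Afatinib (dose S₁) scales IP₃ production: `D₁ = 1 − f₁(S₁)`.  RP4010
(dose S₂) blocks SOCE.  The published factor for the SOCE term is
printed as `D₂ = 1 − f₂(S₂) − f₃(S₁)`, but that sign convention is
inconsistent with the rest of the published results in two independent
ways:

1. the published sensitivity table reports PRCC(c₃) = −0.541 (increasing
   the crosstalk strength *shortens* the period) and PRCC(k₃) = +0.374 —
   both are the reverse of what a `−f₃` term implies and exactly what a
   `+f₃` term implies;
2. with `−f₃`, a faithful simulation gives 69.8 s at 0.5 µM afatinib
   (published: 47.4 s) and kills the oscillation entirely at the
   2 µM + 1 µM combination (published: 92.8 s); with `+f₃` the same
   simulations give 46.9 s and 93.6 s.

Every structural alternative (D₁ applied to the whole IP₃ equation, D₁
applied to the IP₃R density k_f, clamped and unclamped D₂, both f₃
signs) was screened against all six published simulated periods; only
`D₂ = 1 − f₂(S₂) + f₃(S₁)` reproduces them.  The package therefore uses
the `+f₃` convention.  Consequences: D₂ is non-increasing in S₂,
non-decreasing in S₁, never negative by construction at the fitted
constants (a floor at 0 is applied for safety), and may exceed 1 — it is
a channel-availability *scale*, not a probability.  D₁ stays in [0, 1].

### The two unprinted constants

`p_s` (steady-state IP₃) and `k_β` never appear in the published
parameter table.  `k_β` keeps the source-model value 0.4.  `p_s` is
calibrated so that the untreated model oscillates at the measured control
period of 32.8 s; the shipped value is **p_s = 0.1004 µM**.  The pair
(k_β, p_s) is degenerate: p enters P_O only through the odds `(p/K_p)²`
weighted by k_β, so refitting p_s at any k_β in [0.2, 6] reproduces the
control period with drug responses unchanged to three decimal places.
The calibration is therefore effectively one-dimensional, and the
commonly used source value of k_β is as good as any point on the family.

## Parameters

The kinetic constants ship in `caoscsim/data/params_kyse150.yaml`
(µM, s): δ=1.5, K_τ=0.1, K_c=0.2, k_f=3.9 s⁻¹, V_serca=0.9, γ=5.5,
V_pm=0.11, α₀=0.0027, K_p=0.2, τ_max=1420 s, β_p=0.027 s⁻¹, K_h=0.08,
K̄=1.9e−5, K_e=8, K_pm=0.3, α₁=0.385, plus the calibrated p_s=0.1004 and
k_β=0.4.  Two reading notes:

* **τ_max units**: the published units column prints s⁻¹, but
  `dh/dt = (h∞ − h)/τ_h` requires τ_h to be a time; τ_max is implemented
  as 1420 s.  (The alternative reading — a rate of 1420 s⁻¹ — makes `h`
  instantaneous and removes the oscillation mechanism entirely.)
* **SERCA half-saturation**: the printed J_serca denominator reuses the
  symbol k_p; the package carries two independent fields with the same
  default 0.2 µM (`K_p` for the IP₃ dependence, `k_serca_half` for
  J_serca) so they can be varied separately.

The Het-1A (non-tumorous) set divides k_f by 5 and α₁ by 3, nothing else.

Drug constants (`c₁=0.51, c₂=1, c₃=0.76, k₁=0.34, k₂=0.6, k₃=0.8 µM`)
are the published fitted values; c_i are fractional maximal effects
(bounded [0, 1] in fits), k_i half-effect doses (bounds [0.01, 100] µM).

## Numerics

* **Integration**: LSODA (adaptive, stiffness-switching) is the default
  backend; a compiled Dormand–Prince 5(4) integrator is used for ensemble
  work (~3 ms per trajectory).  The two agree on the period to < 0.1%
  (asserted in tests).  Default tolerances rtol 1e−7 / atol 1e−9; the
  period changes by < 0.1% when rtol is tightened from 1e−6 to 1e−8.
* **Slow limit cycles**: the Het-1A cycle (~540 s) is tolerance-sensitive
  at the defaults — LSODA and RK45 land on different nearby readings
  (533 vs 542 s).  At rtol 1e−9 both, and an independent implicit Radau
  run, agree on 541.7 s (interval sd 0.01 s).  Long-period runs therefore
  use rtol 1e−9 / atol 1e−12 over a 30 000 s window with an 8 000 s
  transient.  The value sits ~10% below the published 600.9 s — the
  long-period regime amplifies whatever small differences remain between
  this reconstruction of P_O and the original implementation.
* **Initial conditions** (not published): c=0.1 µM, c_e=10 µM, h=h∞(c),
  p=p_s, with a 1 000 s transient discarded.  The extracted period is
  insensitive to this choice to < 0.1% (tested).
* **Period extraction**: peaks of c(t) on a 0.25 s output grid with a
  prominence threshold of 10% of the post-transient amplitude range
  (rejects solver ripple, keeps true spikes); peak times are refined by
  local parabolic interpolation; the period is the mean of successive
  peak intervals.  Fewer than 3 peaks, or a peak-to-trough range under
  1e−3 µM, classifies the window as non-oscillating; the period is then
  reported as absent, never infinite.  Notably, no finite dose kills the
  oscillation at the fitted constants — extreme SOCE block slows the
  cycle to ~600 s — so the non-oscillating path arises in practice from
  observation windows shorter than 3 cycles, as it would in a 5-minute
  imaging recording.
* **Problem sizes**: routine simulations use a 4 000 s horizon (~90
  cycles at baseline), drugged doses 6 000 s (~45–130 cycles), so the
  mean period averages enough intervals that grid effects are negligible.

## Calibration

Fitting is staged: baseline kinetics first (control period; any of k_f,
α₁, τ_max, V_serca, p_s may be freed, log-scaled, trust-region least
squares), then the six drug constants against dose–period tables with the
baseline frozen.  Joint fitting across tables is available by passing
several tables.  Residuals are unweighted by default (SEM weighting
optional); trial points that kill the oscillation at some dose receive a
penalty residual of 10× the largest observed period, which keeps the
objective finite across oscillation-death boundaries.  On noise-free
synthetic tables generated by the model itself, all six drug constants
are recovered to < 1% from a perturbed start; with period noise at the
measured SEM scale, the RP4010 efficacy c₂ is recovered with < 15% median
relative error over 20 replicates (both asserted in tests).

## Sensitivity analysis

Latin hypercube sampling over the eight constants {k_f, α₁, c₁, c₂, c₃,
k₁, k₂, k₃}: each marginal is a Weibull with shape 5 and scale chosen so
the mean equals the baseline (CV ≈ 23%, positive support by
construction) — the published analysis states a Weibull but not its
parameterization, so this is the package's choice, exposed as an
argument.  M = 500 by default (M is likewise unpublished).  Sampled c_i
above 1 are applied as sampled (a stronger-than-baseline maximal effect),
not clamped.  Non-oscillating rows are censored at twice the largest
observed period, preserving their rank as "slowest"; the censored
fraction is reported (≈ 0.5–1% at the published analysis dose).  PRCC is
computed by rank-transforming design and response and correlating the
residuals after linearly removing the other seven rank columns; p-values
use the partial-correlation t statistic on M − 2 − 7 degrees of freedom.

At the published dose (0.5 µM afatinib + 1.0 µM RP4010) the package
reproduces the published sensitivity structure for the six drug-layer
constants — α₁ strongly negative (≈ −0.76 vs published −0.831), c₂
strongly positive (≈ +0.73 vs 0.812), c₃ negative, k₂ negative, k₃
positive, k₁ weakly negative — but finds k_f and c₁ strongly sensitive
(|PRCC| ≈ 0.8–0.86) where the published table reports them as noise
(p = 0.64 and 0.27).  A period-setting release-scale k_f that is
*insensitive* is irreconcilable with the same parameter being the lever
that slows the Het-1A variant tenfold; the likely explanation is that the
published ensemble never propagated those two sampled columns into the
simulation.  This package reports what the model implies.

## Synthetic cohorts and trimming

`synthesize_periods` emulates a live-cell imaging experiment: per-cell
periods are the deterministic model period at the dose plus truncated
Gaussian noise (default sd 9.5 s per cell, giving a ~1.3 s SEM over a
50-cell group, the scale of the measured tables).  It reproduces the
mean ± SEM *structure* of real cohorts but none of their biology — no
cell-cycle heterogeneity, no non-Gaussian tails, no correlated drift — so
recovery tests passing on these cohorts demonstrate the estimator
machinery, not robustness to real-data pathologies.  Group summaries
apply the 1.5×IQR fence rule (linear-interpolation quartiles) before
averaging, and record group sizes before and after trimming.  The rule is
applied once, as in the published procedure; it is not mathematically
idempotent on adversarial samples (removing points shrinks the
quartiles), and the tests pin the fence-partition behaviour instead.

## Synergy scoring

Median-effect lines are fitted by least squares in log-odds/log-dose
coordinates; the combination index uses the classic mutually exclusive
form `CI = D₁/Dx₁ + D₂/Dx₂` without the third (nonexclusive) term.  For
period readouts the fraction affected is `fa = (T − T₀)/(T_plateau − T₀)`
with T₀ the drug-free period and T_plateau defaulting to 1.1× the largest
observed period — the original analyses were run through external
software whose effect transform for period data is not described, so this
mapping is a convention of this package.  Under it, the fitted model's
2:1 combination ray scores CI < 1 at every dose, consistent with the
dominance of the combination dose–response curve over both single-agent
curves.

## Known limitations

* The model reproduces oscillation frequency, not amplitude or spike
  shape, and contains no spatial or stochastic effects.
* The Het-1A period lands ~10% short of the published value; the
  long-period regime is the most sensitive to the reconstructed P_O
  constants.
* The simulated low-dose combination periods (≈ 39–61 s) undershoot the
  measured ones (≈ 60–64 s): saturating Michaelis–Menten effects with
  the published constants cannot produce the steep initial rise the
  measurements show, which caps the pooled model-vs-data rank correlation
  near 0.92 over the full dose grid.
* PRCC magnitudes depend mildly on the (unpublished) Weibull spread and
  censoring convention; signs and the sensitive/insensitive split of the
  drug-layer constants do not.
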