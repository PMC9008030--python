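# Methods

This note documents the models and procedures implemented in `spinefate`,
the assumptions behind them, the choices made where a design was genuinely
open, and what the synthetic-data generators do and do not emulate.

## Spine dynamics

A fate matrix is a tidy table of (mouse, dendrite, spine, session day,
present) records. All dynamics statistics derive from it:

* **Density**: spines present per micron of dendrite, per session.
* **Turnover ratio**: R = (gained + lost)/(N_ti + N_tj) for consecutive
  session pairs of each dendrite's own schedule. A spine present at exactly
  one interior session counts once as gained and once as lost in the two
  flanking intervals (the literal reading of the definition). The "4-day
  TOR" helper (`TurnoverResult.with_spacing(4)`) selects pairs with exactly
  4-day spacing; longer intervals are reported separately, never pooled or
  rescaled — whether rescaling is appropriate depends on the (unknown)
  hazard shape, so both outputs are left to the user.
* **Survival fraction**: SF(t) = (N0 − cumulative losses)/N0, where loss is
  *absorbing*: once a spine is scored absent it stays lost even if a
  protrusion later reappears at that position. Reappearances should be
  annotated as new spine ids; this matches the cumulative-loss definition
  of SF. For the new-spine cohort each spine's clock starts at its first
  present session, and SF at relative time t is computed among spines whose
  dendrite was still imaged t days after entry, so right-censored spines
  never count as losses.
* **Event records**: an event is placed AT the first session where the
  spine is scored absent (not the interval midpoint); spines present at the
  last session are censored there. This is conservative and matches how SF
  is tabulated at session days; it is an interval-censoring approximation,
  and discrete session days therefore produce heavily tied event times.

## Survival models

**Exponential decomposition.** Mouse-averaged (or pooled) SF points are
fitted with a·e^{bt} and a·e^{bt} + c·e^{dt} by bounded nonlinear least
squares (amplitudes ≥ 0, rates ≤ 0). The amplitudes are *not* constrained
to sum to one — fitted decompositions of empirical survival curves
routinely sum slightly above 1 — so `fit_exponential` accepts SF values up
to 1.05. The two-exponential fit is multimodal in the rates, so a
deterministic multistart is used: rate grid b ∈ {−0.5, −0.2, −0.1} ×
d ∈ {−0.05, −0.01, −0.001}, amplitudes initialised by a linear solve at the
fixed rates, best RSS wins (first-in-grid on ties). Components are reported
fast-first (b ≤ d).

**Model selection.** AIC uses the Gaussian-error likelihood of the NLS fit:
AIC = n·ln(2π·RSS/n) + n + 2(k_model + 1), counting the error variance as a
parameter (k = 3 for the single, 5 for the double exponential), matching
the convention of standard statistics software. cAIC adds
2k(k+1)/(n − k − 1), defined only for n > k + 1.

**Kaplan-Meier.** The product-limit estimate comes from lifelines; the 95%
band uses the Greenwood variance on the log-survival scale
(S·exp(±z·√Σd/(n(n−d)))), with the plain-scale Greenwood band available by
flag. Records censored at an event time count as at risk for that event.

**Cox proportional hazards.** Two-group comparison h(x,t) = h₀(t)·e^{bx}
via lifelines with Efron tie handling (ties are heavy because events sit on
session days; Breslow would be noticeably biased). Robust Huber-White
standard errors are clustered by mouse; the naive SE is reported alongside.
With singleton clusters the clustered sandwich reduces to the ordinary
heteroskedasticity-consistent robust SE (tested). Complete separation
surfaces as a convergence error with diagnostics.

**Density trend.** Density ~ time is fitted by REML with a random intercept
per mouse and a variance component for dendrite nested in mouse
(statsmodels MixedLM). The time effect is tested with a Wald t using a
containment degrees-of-freedom rule, df = N − #dendrites − 2, recorded in
the result metadata (a Satterthwaite approximation is not available in the
backend; containment is the conservative classical fallback). A single
dendrite falls back to ordinary regression with a warning.

Note on homeostatic simulations: counts produced by the birth-death
generator are serially correlated within a realization (a martingale), so a
per-realization trend test on them is anti-conservative by construction.
The generator's homeostasis is therefore asserted on the across-seed mean
slope, and the trend model's coverage is validated on stationary density
tables with independent session noise.

## Marker classification

**Thresholding.** The Kapur-Sahoo-Wong threshold maximises the summed
Shannon entropies of the background (levels ≤ t) and foreground (> t)
histogram halves; ties break toward the lowest level. It is implemented
directly (scikit-image does not ship it) and is tested for exact equality
with an exhaustive search.

**Segmentation.** GFP threshold → binary mask → Gaussian blur of the mask
(σ = 2.5 µm converted to pixels; skipped with a warning below half a pixel)
scaled to the image grey range and re-binarised with the *same* threshold —
this keeps the threshold dimensionally applicable to the blurred mask; the
documented alternative of blurring the raw image is deliberately not the
default because it changes which pixels are foreground. Connected
components are then watershed-split using distance-transform peaks at least
half a minimal-ROI diameter apart (a physical scale — heavily overlapping
somata can remain near-convex, so solidity alone is an unreliable merge
flag; a single-peak component is returned whole, making the split
idempotent for isolated cells). ROIs below 25 µm² are discarded.

**Features.** Per ROI × channel: integral of brightness above threshold
(Σ(I − t) over above-threshold pixels — the excess-mass reading, which is
exactly zero for a ROI sitting at threshold; the raw Σ I variant is
available), percentage of pixels above threshold, minimum brightness above
threshold (0 with an indicator column when no pixel qualifies), and mean
brightness. Thresholds are computed independently per channel: a GFP-derived
level has no meaning on another channel's intensity scale. GFP offsets
(mean, % area above threshold, integral) enter the model as fixed ln(Z)
terms. Within-channel 2- and 3-way interactions of the four base features
are generated on request; cross-channel interactions are not the default.

**Bayesian positivity model.** Outcome o_i ~ Bernoulli(p_i) with
logit(p_i) = α_slice + b_d + Σβ_j·Y_ij + offsets; α_slice ~ Normal(0, σ),
σ ~ half-StudentT(3, 0, 10); β_j ~ Normal(0, 1) on the standardized
predictor scale (coefficients are back-transformed for reporting); marker
coefficients b_d ~ Normal(logit(p_d), 1) with literature co-expression
rates p_d clipped to [0.05, 0.95] (the SST rate is the geometric mean of
reported values with zeros floored at 0.05, ≈ 0.108). The default prior
table carries the published rounded logits (e.g. CCK −1.61 = logit(1/6)
rather than logit(0.17) = −1.586); exact logits come from `build_priors`.
The posterior is sampled with an affine-invariant ensemble sampler (emcee,
differential-evolution moves, non-centered slice intercepts, log-σ with
Jacobian), walkers grouped into pseudo-chains for rank-normalised R-hat and
ESS; the fit raises if any R-hat exceeds 1.05. The sampler is pluggable in
the sense that results depend only on the posterior definition and the
diagnostic thresholds. Identifiability note: with a single marker level and
few slices, the marker coefficient and the slice intercepts are confounded;
informative priors and many slices (as in realistic designs) resolve this.

**Evaluation.** ROC by threshold sweep on per-ROI posterior positivity;
the trapezoidal AUC equals the Mann-Whitney U statistic over positive ×
negative pairs (tested against brute-force pair counting).

## Electrophysiology metrics

Sag = |minimum voltage during the hyperpolarising step − steady state|,
with steady state the mean over the last 20% of the step (the definition
says only "steady state"; the window length is a documented choice).
Rebound = maximum post-step depolarisation above the resting baseline.
APs are detected where dV/dt > 20 mV/ms (no published threshold; this
value is configurable); amplitude is peak minus threshold-crossing voltage,
AHP the deepest repolarisation below the AP threshold, ADP the subsequent
local maximum. The first ISI at rheobase is reported as the burst metric —
no cutoff is imposed; classification is left to the user. Accommodation
index = mean(ISI 2..4)/mean(last 3 ISIs) (a ratio of sums would be
identical). Passive fits are bi-exponential in log-τ with a deterministic
multistart; capacitance = transient charge integral / |ΔV| (pA·ms/mV = pF)
and input resistance = ΔV / steady-state current change. EPSC events are
detected as threshold crossings of the inward deviation from the median
baseline with a refractory gap; the 10-90% rise time of the averaged event
uses linear interpolation between samples. All difference-based metrics are
invariant to baseline offsets (tested). Mann-Whitney comparisons use the
exact null for min(n) ≤ 8 without ties, otherwise the tie-corrected normal
approximation.

## EM morphometry

Densities are count/length; printed percentages round half-up to integer
percent, matching the formatting of published tables. The synapse-surface to
spine-volume ratio sums the surfaces of a spine's excitatory synapses before
dividing — the only definition consistent with multi-synapse spines
reported as one number per spine. A compound (redundant) connection is an
axon with ≥ 2 synapses on the *same* dendritic segment; contacts on
different dendrites do not qualify. t-tests default to Welch (the group
variances in real tables differ several-fold) with the pooled-variance
Student variant available, and accept either raw vectors or (mean, sd, n)
summaries.

## Synthetic-data generators

All randomness flows from one integer seed through named CRC32-keyed
substreams, so each generator is independently reproducible and identical
seeds give bit-identical output.

* **Spine cohorts**: each day-0 spine draws a class (fast with probability
  0.59/1.01 ≈ 0.584 by default, the published two-exponential amplitudes
  normalised so survival starts at 1) and an exponential lifetime at rate
  0.13/day (fast) or 0.02/day (slow); imaging discretizes the continuous
  lifetimes onto the observation schedule (default: 4-day grid to day 54,
  16 dendrites, 5 mice, 0.75 spines/µm — the published study scale;
  irregular schedules are supported). With homeostatic gains on, births per
  interval are Poisson with mean equal to the expected losses inflated by
  the probability that a newborn survives to the next session, so the
  *observed* count is stationary in expectation (newborns dying within the
  interval are unobservable transients). New spines default to the day-0
  mixture but can have their own mixing/rates, since new-spine survival is
  reported separately in practice. The pyramidal comparison cohort uses the
  published amplitudes 0.16/0.84 with rates 0.21 and 0.001/day — the slow
  rate prints as 0.00 but lifetimes must be finite, so a small positive
  hazard stands in.
* **Images**: Gaussian somata (σ = radius/2) on a uniform background;
  marker channels are bright over a cell iff it was drawn positive at the
  panel's co-expression rate; touching cells are placed about one diameter
  apart so thresholded masks overlap at their margins. Noise is Gaussian by
  default (deterministic SNR control), with a Poisson shot-noise toggle.
  Not emulated: dendrites/neurites, PSF anisotropy, bleed-through, motion —
  so passing segmentation tests demonstrate the pipeline's logic, not
  robustness to those artefacts.
* **Ephys sweeps**: constructed so the named metric is exact — sag/rebound
  as on-grid alpha transients of the requested amplitude, passive
  transients as explicit two-exponential sums (optionally scaled to a
  target charge), EPSCs as alpha events whose time constant is solved from
  the requested 10-90% rise.
* **EM tables**: truncated-normal sizes per group (defaults follow the
  published group summaries), configurable class mix, spine/shaft
  placement, ER/MSB rates, and axon ids paired so a target fraction of
  synapses forms compound connections.

## Numerical conventions and limitations

Pixel coordinates are 0-based (row, col); images are written as multi-page
TIFF with pixel size in the resolution tags and the channel map in the
description. Tables are tidy long-format CSV; fate matrices are one row per
spine-session, robust to irregular schedules. Reported problem sizes in the
test and acceptance runs (e.g. 1000-spine cohorts, 20 replicates, 64×64
threshold-oracle images) were chosen as the smallest scales at which the
Monte-Carlo tolerances derived from binomial/normal error propagation are
meaningful. Known limitations: no time-varying covariates or frailty terms
in the Cox model; no parametric survival regression beyond the exponential
sums; no image-based spine detection (annotation is an input); no
confocal-specific corrections; EM sizes are inputs, not computed from
volumes.
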