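# spinefate

Quantitative analysis of longitudinal dendritic-spine dynamics on cortical
VIP interneurons, with the companion analyses used to characterise that cell
population: survival modelling of spine cohorts, Bayesian immunofluorescence
marker classification, intrinsic/synaptic electrophysiology metrics and EM
morphometry summaries. Every analysis is exercisable end-to-end on synthetic
data generated in-package, so the full pipeline runs without any external
download.

Intended users: neuroscientists analysing chronic two-photon spine-tracking
experiments (annotation tables of spine presence per imaging session), and
anyone needing the companion statistics (maximum-entropy ROI segmentation,
hierarchical logistic marker models, patch-clamp metric extraction,
EM reconstruction summaries) in reusable, tested form.

## The statistics at the core

**Spine dynamics.** From a *fate matrix* (spine × session presence records
with dendrite and mouse identifiers), the package computes the linear spine
density, the turnover ratio between consecutive sessions

    R(t_i, t_j) = (N_gained + N_lost) / (N_{t_i} + N_{t_j}),

and the survival fraction of a cohort

    SF(t_i) = (N_0 − N_lost(0, t_i)) / N_0,

where loss is absorbing (a protrusion reappearing at the position of a lost
spine is a new spine). Cohorts can be the day-0 spines or newly formed
spines, whose clock starts at first appearance.

**Survival models.** Mouse-averaged survival fractions are fitted with
single (a·e^{bt}) and two-exponential-sum (a·e^{bt} + c·e^{dt}) decay
functions by nonlinear least squares; model choice uses the corrected
Akaike Information Criterion, cAIC = AIC + 2k(k+1)/(n−k−1). Spine-level
event records feed a Kaplan-Meier estimator (Greenwood confidence bands)
and a Cox proportional-hazards comparison h(x,t) = h₀(t)·e^{bx} between
two cell classes, with Efron tie handling and Huber-White standard errors
clustered by mouse. Density trends over time are tested with a linear
mixed-effects model (random intercepts for mouse and dendrite-in-mouse).

**Marker classification.** Cell-body ROIs are segmented on the GFP channel
(Kapur-Sahoo-Wong maximum-entropy threshold, mask blur at σ = 2.5 µm,
watershed splitting of touching cells, ROIs < 25 µm² discarded); per-channel
brightness features enter a Bayesian hierarchical logistic model

    o_i ~ Bernoulli(p_i),  logit(p_i) = α_slice + b_d + Σ_j β_j Y_ij + Σ_k ln(Z_ik)

with informative logit-scale priors on the marker coefficients b_d derived
from literature co-expression rates (e.g. b_VIP ~ Normal(3, 1)), sampled by
MCMC with R-hat/ESS diagnostics, and evaluated by ROC/AUC.

**Ephys & EM.** Sweep-level extraction of sag, rebound, AP shape (amplitude,
AHP, ADP), ISI/burst/accommodation metrics, bi-exponential passive fits
(τ_fast, τ_slow, capacitance from the charge integral, input resistance) and
EPSC amplitude/frequency/10-90% rise; Mann-Whitney group comparisons. EM
tables are summarised into synapse densities, class fractions, size ratios,
and compound-connection (axons with ≥ 2 contacts on one dendrite) counts,
with Welch/Student t-tests.

## Worked example

```python
from spinefate.simulate import SpineSimParams, simulate_spine_cohort
from spinefate.dynamics import survival_fraction
from spinefate.survival import fit_exponential

# 10 dendrites x 100 day-0 spines from a two-population lifetime mixture
params = SpineSimParams(
    fast_fraction=0.59 / 1.01, fast_rate=0.13, slow_rate=0.02,
    gain_mode=False, n_dendrites=10, spines_per_dendrite=100, seed=1,
)
fm, truth = simulate_spine_cohort(params)
sf = survival_fraction(fm, cohort="day0").pooled()
fit = fit_exponential(sf["time_days"], sf["sf"], model="two_sum")
print([round(p, 3) for p in fit.params], round(fit.caic, 1))
```

prints

```
[0.478, -0.146, 0.521, -0.024] -102.0
```

i.e. the fit decomposes the simulated cohort into a fast population
(amplitude 0.48, decay 0.15/day) and a slow population (0.52, 0.024/day) —
a single 1000-spine cohort scatters around the generating mixture
(0.58/0.42 at 0.13 and 0.02/day); averaged over replicates the fast
amplitude centres on it — and reports the corrected-AIC score used for
model selection.

The same pipeline runs from the shell:

```bash
spinefate run --seed 1 --out out/        # simulate -> dynamics -> survival
spinefate simulate --seed 1 --out sim/   # fate-matrix CSV + ground truth
spinefate dynamics --fate-matrix sim/fate_matrix.csv \
    --lengths sim/dendrite_lengths.csv --out dyn/
spinefate survival --events dyn/events.csv --out surv/
```

`out/results.json` collects the fitted decay parameters, the AIC/cAIC table,
the density-trend test and the Cox hazard ratio between the simulated VIP
and pyramidal cohorts; `manifest.json` records the seed and checksums of
every artifact.

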