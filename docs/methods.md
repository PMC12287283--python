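# Methods

`enadecay` estimates decay kinetics of environmental nucleic acids (eNA) from
digital droplet PCR (ddPCR) droplet counts, end to end: droplet occupancy →
absolute concentration → hierarchical Bayesian biphasic decay fit → model
comparison → time-sensitive ratio ("molecular clock") summaries. This note
records the model, its assumptions, the defaults and why, and what the
synthetic experiment does and does not establish.

## Observation model

ddPCR partitions a 22 µL reaction into ~20,000 droplets of ~0.85 nL. Target
molecules load droplets as a Poisson process, so a well with `U` droplets and
`W` positives is modelled as

    W ~ Binomial(U, p),      cloglog(p) = ln(mu),

where `mu` is the mean copies per droplet; `cloglog(p) = ln(−ln(1−p))`, i.e.
`p = 1 − exp(−mu)`. Working at the count level (rather than on per-well point
estimates) propagates droplet-level uncertainty into every downstream rate.

`mu` connects to the source-water concentration `C` (copies/L) through the
laboratory volume chain

    mu = C · dvol · tvol · filt / (rvol · evol · d),

with `rvol` = 22 µL reaction, `tvol` = 2 µL template, `evol` = 50 µL elution,
`dvol` = 8.5e−4 µL droplet, `filt` = litres filtered (nominal 2), and `d` ≥ 1
a sample-specific template dilution (e.g. from the reverse-transcription
reaction; default 2 for RNA-derived wells, 1 otherwise). Each factor is
exposed separately so the conversion is auditable; the implementation is the
dimensionally consistent chain verified by an exact round-trip identity and
by Monte-Carlo re-estimation from simulated droplets. Saturated wells
(`W = U`) have unbounded `mu`; they stay in the binomial likelihood (which
handles `p → 1`) but are flagged and excluded from point-estimate tables.

Absolute RNA concentrations are conditional on 100% reverse-transcription
efficiency; RT losses are not modelled, as they are not separable from `C`
with this design.

## Screening rules

**No-RT subtraction.** Reverse-transcription controls without the enzyme
(No-RT) quantify residual DNA in RNA extracts. The No-RT positive-droplet
count of the same sample is subtracted from the paired eRNA count at the
droplet-count level, floored at zero, and logged per well.

**Pore-size screen.** When serial-filtration fractions are present, the
fraction of total signal per pore size is computed at the earliest timepoint;
if one pore size captures more than a configurable threshold (default 0.95)
of the signal in every biological replicate, analysis is restricted to that
fraction. Under the defaults the 5 µm fraction dominates and is the one
analysed.

## Duplex linkage ("Bridge") quantification

A duplex assay reads 16S and D-loop in the same droplets. Because mtDNA is
circular, molecules of at least 2746 bp (up to the full ~16.4 kb mitogenome)
carry both amplicons and always produce double-positive droplets; fragmented
molecules co-occur only by chance. With independent Poisson loads
(λa, λb, λL) for free-16S, free-D-loop and linked molecules, the four droplet
categories have closed-form probabilities; writing `qA`, `qB`, `q00` for the
A-negative, B-negative and double-negative fractions,

    λL = ln q00 − ln qA − ln qB,
    λa = −ln qA − λL,   λb = −ln qB − λL.

This inversion is exact (tested to 1e−12) and is the default estimator. The
subtraction heuristic — observed double positives minus `U(1−qA)(1−qB)`
expected under independence, divided by `U` — is also implemented: it agrees
with the closed form at low occupancy but underestimates λL materially at
high occupancy (e.g. ≈0.067 vs 0.2 at loads (0.5, 0.3, 0.2)), which the test
suite documents. In the Bayesian fit, duplex wells enter as a four-category
multinomial parameterized by (λa, λb, λL), each tied to its own decay curve,
so Bridge rates carry droplet-level uncertainty rather than being plugged in
from per-well estimates.

## Decay model and priors

The primary model is the biphasic exponential with a changepoint:

    C(t) = C0 · exp(−λ1 t)                      t < t_x
    C(t) = C0 · exp(−λ1 t_x) · exp(−λ2 (t−t_x)) t ≥ t_x

per marker-component: λ1, λ2 (1/h) and t_x (h) are shared across the three
biological replicates (carboys); C0 is carboy-specific. A menu of five
alternatives spans the empirical decay-curve families used for eDNA: single
exponential, exponential plus constant residual, Weibull (stretched
exponential), Hill-type power law, and a two-pool exponential mixture. All
are closed-form, non-increasing in time, and dispatched through one
`DecayModelSpec` interface so the LOO machinery is model-agnostic.

Priors (all proper, all config-overridable):

- `ln C0` ~ Normal(m, 3) per carboy, with `m` a method-of-moments estimate
  from the earliest timepoint. Three log-units of sd is diffuse relative to
  any plausible C0 misestimate; the data dominate.
- rates (λ1, λ2, and analogues) ~ half-Normal(0, 1 h⁻¹): weakly informative,
  admitting anything from effectively stable to ~40 min half-life.
- `t_x` ~ Uniform(12, 96) h, truncated to the observed time range. The
  transition is only weakly identified when it falls inside the 24–48 h
  sampling gap, so its posterior is prior-sensitive by design of the
  experiment; the bounds bracket the gap generously.
- No λ2 < λ1 ordering is imposed by default — the biphasic shape must come
  from the data; an ordering constraint is available as a config option.

**Identifiability rule.** A component with no detections at any timepoint
after its first detected timepoint (e.g. messenger RNA detected once and
never again) cannot identify a changepoint or a second rate. Such components
are reduced to the single-exponential model and reported with NA for
t_x/λ2 — a detection-based rule, not a posterior heuristic. This also keeps
parameters with no information out of the convergence diagnostics.

## Sampling and diagnostics

The posterior is sampled with affine-invariant ensemble MCMC (emcee). Fit
groups (each monoplex marker-component; the duplex trio jointly) share no
parameters and are sampled independently. A "chain" is one independent
ensemble (≥32 walkers) whose post-warmup states are thinned and flattened;
four such chains support rank-normalized split R-hat and bulk ESS (arviz).
Proposals mix differential-evolution (0.6), snooker (0.2) and stretch (0.2)
moves: DE follows the correlated (ln C0, λ1, t_x) geometry, while the
stretch component contracts stragglers from the deliberately over-dispersed
initial ensemble. Walkers start at the method-of-moments point with half a
log-unit of scatter on magnitudes; `t_x` starts inside the 24–48 h sampling
gap, where the transition physically lives — ensembles started across the
full prior range occasionally settle into a metastable late-transition mode
that only very long warmups escape.

Default sampler settings are 4 chains × (1000 warmup steps + 2000 retained
draws); production settings (used by the acceptance script and the
diagnostics tests) are 4 × (5000 + 10,000), which on the default synthetic
experiment give max R-hat < 1.005 and min bulk ESS well above 500. The
thinning stride (4 ensemble steps) keeps retained draws close to
independent. Non-convergence never fails silently: diagnostics are computed
for every parameter and the pipeline flags (and exits nonzero on) threshold
violations.

Model comparison uses PSIS leave-one-out cross-validation on the pointwise
well-level log-likelihood (arviz PSIS). Wells whose log-likelihood is
numerically constant across draws — far below the detection limit — have
exact LOO contributions and are handled outside the importance sampler,
which otherwise degenerates on zero-variance weights. The comparison table
reports each model's elpd with SE, and differences to the best model with
the SE of the paired per-well differences.

## Molecular clocks

Two ratios index time since nucleic-acid release: the proportion of long
(Bridge) to short (Cytb) mitochondrial fragments, and the proportion of
ribosomal eRNA to total 16S nucleic acids. Ratios are computed per posterior
draw on a 0–24 h grid (0.5 h step), then summarized as the median and
2.5/97.5% quantiles per timepoint and carboy — draw-then-summarize, never a
ratio of summaries. Draws with a vanishing denominator are excluded and
counted. The trend is condensed into an unweighted OLS slope on the pooled
per-carboy posterior-median trajectories; its p-value is reported but
labelled heuristic, as the grid points are strongly autocorrelated. The
Bridge proportion is `C_Bridge / C_Cytb` by default (the Bridge is excluded
from the denominator); a spec flag switches to `Bridge/(Bridge+Cytb)`.
Ratio inversion into explicit age estimates is out of scope: under
multi-pulse shedding the mapping from ratio to age is confounded.

## Synthetic experiment

The generator emulates the mesocosm design at droplet level: 3 seawater
carboys + 1 deionized-water control, nine timepoints (0, 4, 8, 12, 24, 48,
96, 140, 188 h) plus a pre-transport baseline at −3 h, two technical
replicates, 20,000 droplets per well, the full volume chain, duplex
multinomial draws for 16S/D-loop/Bridge, No-RT controls with Poisson(0.5)
residual positives, and a 3-stage serial-filtration screen at the first
timepoint allocating (0.96, 0.025, 0.015) of the signal to the 5/1/0.45 µm
filters. Actual filtration times add Uniform(0, 0.25 h) jitter per sample.

Default truth values are the study conditions: per-component (λ1, λ2, t_x)
set to the reported posterior estimates (Cytb eDNA 0.114/0.026/41; 16S eDNA
0.165/0.028/33; 16S erRNA 0.236/0.054/29; D-loop 0.166/0.021/36; Bridge
0.190/0.044/28 h⁻¹/h⁻¹/h; Cytb emRNA 1.615 h⁻¹, single-phase). Initial
concentrations are not reported, so they were derived once from the reported
0–24 h clock slopes: an OLS slope of −0.0036 h⁻¹ for a ratio decaying at
(0.190 − 0.114) h⁻¹ implies a Bridge:Cytb starting proportion of ≈0.11, and
−0.0142 h⁻¹ at (0.236 − 0.165) h⁻¹ implies an erRNA proportion of ≈0.5;
absolute scale (Cytb 3e5 copies/L) puts t=0 occupancies in the informative
ddPCR range. The messenger-RNA C0 (500 copies/L) makes it detectable only at
the first timepoint, matching its single-detection-then-loss behaviour.
Carboy heterogeneity is a lognormal multiplier (sd 0.2) on C0 per
carboy-component — exactly the structure the inference model assumes; a
mis-specification mode with carboy-specific rates exists for robustness
experiments.

What passing tests show: the estimators are exact where they claim to be,
the Bayesian machinery is calibrated (≈95% interval coverage over repeated
synthetic experiments), model selection recovers the generating family, and
the full chain reproduces the study-condition rates and clock slopes from
raw droplet counts. What they do not show: robustness to real-data features
the generator omits — PCR inhibition, droplet rain/threshold ambiguity,
plate effects, non-Poisson clumping of template (e.g. aggregates or intact
cells), temperature or microbial covariates, and RT efficiency below 1.

## Numerical choices and conventions

- Clopper–Pearson (exact binomial) 95% intervals for per-well occupancy.
- Negative closed-form duplex estimates are floored at 0 and flagged
  (concentrations are physical); the Bayesian path needs no flooring.
- Multinomial category probabilities are clamped at 1e−300 before logs; a
  zero-probability category with zero count contributes exactly 0.
- `ln C0` is capped at 500 during sampling to avoid overflow excursions.
- The biphasic curve is continuous at t_x by construction; both branches are
  evaluated and selected, so vectorized evaluation is exact at the knot.
- Time is measured from placement in the environmental chamber; baseline
  samples carry negative times and are excluded from decay fits by default
  (config switch to include), since the transport interval is not under
  chamber conditions.
- Fit reproducibility: all chain seeds derive from one `SeedSequence`; the
  same seed and config give bit-identical draws.
- Problem sizes in the test suite are the package's own choices for a
  desk-scale run: unit-level fits use 2 chains × (600 + 600) draws on
  single-marker datasets; calibration uses 50 replicate experiments; the
  diagnostics and reproduction checks run the production 4 × (5000 + 10,000)
  configuration once and share the fit.

## Known limitations

- t_x is prior-sensitive whenever the transition falls in a sampling gap;
  reported t_x should be read with its interval, not as a point fact.
- The subtraction-heuristic Bridge estimator is biased low at high occupancy;
  it is retained for comparability, not inference.
- Ensemble MCMC scales poorly past a few dozen dimensions; the largest group
  here (duplex trio, 18 parameters) is well within range, but adding many
  markers to one joint group would warrant a gradient-based sampler.
- The NA reduction keys on detections after the first detected timepoint;
  intermittent single-droplet detections (e.g. contamination) would defeat
  it, which is why No-RT subtraction runs first.
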