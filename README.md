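# enadecay

Bayesian analysis of differential environmental nucleic-acid (eNA) decay from
digital droplet PCR (ddPCR) droplet counts.

Environmental DNA and RNA shed by aquatic animals degrade at rates that
depend on molecule type and length: messenger RNA vanishes within hours,
ribosomal RNA decays somewhat faster than DNA, and long DNA fragments decay
faster than short ones. Because of these contrasts, the *composition* of the
nucleic-acid pool in a water sample — not just its amount — carries
information about how long ago the genetic material was released. This
package implements the full analysis chain for a mesocosm decay experiment
(replicate carboys of seawater sampled over ~8 days), for researchers who
quantify eNA by ddPCR and want decay rates, model comparison, and
time-sensitive ratio indicators with honest uncertainty.

## The model

A ddPCR well partitions a reaction into `U` ≈ 20,000 droplets; `W` of them
are positive. Under Poisson loading,

    W ~ Binomial(U, p),   cloglog(p) = ln(μ),

with μ the mean copies per droplet, linked to the source-water concentration
`C` (copies/L) by the volume chain
`μ = C·dvol·tvol·filt / (rvol·evol·d)`. Concentrations follow a biphasic
exponential decay with a changepoint,

    C(t) = C₀·e^{−λ₁t}                        t < tₓ
    C(t) = C₀·e^{−λ₁tₓ}·e^{−λ₂(t−tₓ)}         t ≥ tₓ,

with rates shared across biological replicates and carboy-specific C₀. A
duplex assay reads 16S and D-loop in the same droplets: intact mitochondrial
molecules (≥2746 bp, the "Bridge") always produce double positives, so the
excess of double-positive droplets over chance co-occupancy quantifies
intact mtDNA; the package inverts the four droplet categories exactly and
fits them as a multinomial inside the same Bayesian model. Posteriors are
sampled by ensemble MCMC (emcee) with arviz diagnostics (rank-normalized
split R-hat, bulk ESS) and PSIS-LOO model comparison against five
alternative decay laws. Finally, two "molecular clock" ratios —
Bridge:Cytb fragments and ribosomal-RNA proportion — are computed per
posterior draw over 0–24 h and summarized into slopes.

A synthetic-data module generates the whole experiment at droplet level
(decay truth, duplex linkage, No-RT controls, filtration screen), so the
entire chain runs and is tested without any external data.

## Worked example

```python
from enadecay import (
    generate_fixture, build_dataset, fit_decay_model, summarize_decay,
    MCMCConfig, ratio_trajectory, clock_slope, BRIDGE_TO_CYTB,
)
from enadecay.ddpcr import apply_no_rt_subtraction

bundle = generate_fixture(seed=1)                      # synthetic mesocosm
wells, _ = apply_no_rt_subtraction(bundle["monoplex"])  # No-RT correction
dataset = build_dataset(wells, bundle["duplex"])       # 54 wells per group
draws = fit_decay_model(dataset, "biphasic",
                        mcmc=MCMCConfig.production_scale(), seed=1)
print(summarize_decay(draws).to_string(index=False))
slope = clock_slope(ratio_trajectory(draws, BRIDGE_TO_CYTB))
print(f"Bridge:Cytb clock slope {slope.slope_per_h:+.4f} / h")
```

which prints (a few minutes of sampling):

```
marker component              model  lambda1_mean  lambda1_q2.5  lambda1_q97.5  t_x_median  lambda2_mean                                    na_reason
   16S     erRNA           biphasic      0.237027      0.234434       0.239591   31.122455      0.059258
  Cytb      eDNA           biphasic      0.114020      0.113259       0.114767   41.463716      0.027315
  Cytb     emRNA single_exponential      1.572119      0.903572       2.637810         NaN           NaN no detections after first detected timepoint
   16S      eDNA           biphasic      0.166181      0.164736       0.167643   33.169780      0.026902
 Dloop      eDNA           biphasic      0.166443      0.164685       0.168164   36.334696      0.019199
Bridge      eDNA           biphasic      0.187895      0.183143       0.192908   26.823153      0.047925
Bridge:Cytb clock slope -0.0035 / h
```

Reading the table: short Cytb DNA decays slowest (λ₁ ≈ 0.114 h⁻¹,
half-life ≈ 6 h in phase 1), the long Bridge fragment fastest among DNA
(≈0.19 h⁻¹), ribosomal RNA faster than its DNA counterpart (0.237 vs
0.166 h⁻¹), and all curves flatten into a slow second phase (λ₂ ≈
0.02–0.06 h⁻¹) after a transition at ~27–41 h. Messenger RNA is detected
once and never again, so only a single rate is identifiable and tₓ/λ₂ are
NA. The negative clock slope quantifies how the intact-fragment proportion
declines over the first day.

The same pipeline runs from the shell:

```sh
enadecay simulate --seed 1 --outdir synthetic
enadecay report --config run.yaml        # screen → fit → compare → clocks
```

with a YAML config naming the input CSVs, model menu, priors, sampler
settings and output directory. Outputs are tidy CSVs (fit summary, LOO
table, clock trajectories, per-well concentrations), JSON diagnostics, and
a parquet draws archive, each stamped with the config hash and seed.

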