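# ldmrate

Estimation of bacterial plasmid conjugation rates by the Luria–Delbrück
method (LDM): a fluctuation-style analysis of mating assays that reads the
donor conjugation rate off the probability that a coculture contains *no*
transconjugants, rather than off the number of transconjugants.

The package is for microbiologists and modellers who measure horizontal
gene transfer: it provides the mating model and its first-event theory,
exact and fast stochastic simulators of the assay, the LDM and classical
end-point estimators, the machinery for simulation studies of estimator
accuracy and precision, and a laboratory-facing layer for 96-well
microtiter-plate records (including a synthetic plate generator and a small
CLI).

## The model and the estimators

A well-mixed culture contains donors *D*, recipients *R*, and
transconjugants *T* (densities in cfu/ml), growing at per-capita rates
ψ_D, ψ_R, ψ_T (hr⁻¹), with mass-action plasmid transfer at rates γ_D
(donor→recipient) and γ_T (transconjugant→recipient), in ml·cell⁻¹·hr⁻¹:

    dD/dt = ψ_D D
    dR/dt = ψ_R R − γ_D D R − γ_T T R
    dT/dt = ψ_T T + γ_D D R + γ_T T R

Starting from T₀ = 0, the first transconjugant can only arise from a
donor–recipient conjugation. Treating D and R as deterministic
exponentials and T as a stochastic birth process, the probability that a
1-ml culture is still transconjugant-free at time t̃ is

    p₀(t̃) = exp{ −γ_D D₀ R₀ / (ψ_D + ψ_R) · (e^((ψ_D+ψ_R) t̃) − 1) }.

Inverting for γ_D gives the **LDM estimate**; with p̂₀ the observed
fraction of transconjugant-free parallel cocultures, realized growth
rates, and *f* the reciprocal coculture volume in ml, the laboratory form
is

    γ_D = f · (−ln p̂₀) · (ln D_t̃R_t̃ − ln D₀R₀) / ( t̃ · (D_t̃R_t̃ − D₀R₀) ).

This is exactly the Luria–Delbrück mutation-rate estimate
μ = (−ln p̂₀)·ψ_N / (N₀(e^(ψ_N t̃) − 1)) with the wild-type population
replaced by the donor–recipient pair count (N₀ → D₀R₀,
ψ_N → ψ_D + ψ_R). Because the estimate keys only on the *first*
donor→recipient event, it is unbiased under arbitrary heterogeneity in
growth rates and in γ_T — the regime in which the classical
Simonsen-style end-point estimate (also implemented, as `sim_estimate`)

    γ_D = ψ · ln(1 + (T_t̃/R_t̃)(N_t̃/D_t̃)) / (N_t̃ − N₀)

is inflated by transconjugant self-transfer.

## Worked example

`examples/parameter_recovery.py` simulates 2,000 stochastic mating assays
(ψ = 1 hr⁻¹, γ_D = γ_T = 10⁻⁶, D₀ = R₀ = 10² cfu/ml), batches them 100
per estimate — the block's transconjugant-free fraction supplies p̂₀, one
seeded-random population supplies the densities — with the readout at the
average first-event time:

```
incubation time (average t*): 2.397 hr
fluctuation estimates: 20 (zero: 0, invalid: 0)
median  = 8.94e-07 ml/(cell*hr)
IQR     = [8.48e-07, 9.91e-07]
geomean = 9.06e-07
```

The generating rate was 10⁻⁶: the estimate distribution brackets it, and
the geometric mean lands within ~10% at this scale. The other examples
show the deterministic end-point bias (`deterministic_bias.py`), the
first-event-time distribution against its analytic survival function
(`first_event_distribution.py`), robustness of the LDM median across six
decades of γ_T (`heterogeneity_sweep.py`), and a full plate workflow with
the CLI (`plate_assay.py`):

```
ldm fixtures plate --params assay.yaml --out plate.csv --seed 7
ldm plate validate plate.csv
ldm plate estimate plate.csv
```

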