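# Methods

## The mating model

The package models a well-mixed batch mating assay with three
populations: donors *D* (plasmid-bearing), recipients *R* (plasmid-free),
and transconjugants *T* (recipients that have acquired the plasmid).
Units are fixed throughout: time in hours, densities in cfu/ml,
conjugation rates in ml·cell⁻¹·hr⁻¹. Five rate constants parameterize the
dynamics — per-capita growth rates ψ_D, ψ_R, ψ_T and mass-action transfer
rates γ_D (donor→recipient) and γ_T (transconjugant→recipient):

    dD/dt = ψ_D D
    dR/dt = ψ_R R − γ_D D R − γ_T T R
    dT/dt = ψ_T T + γ_D D R + γ_T T R

Model assumptions, inherited by every estimator in the package:
exponential (resource-unlimited) growth at constant rates over the assay;
no cell death; no segregational plasmid loss (T is a pure birth process);
recipient losses to conversion are negligible for the *recipient*
dynamics whenever γ_D·D ≪ ψ_R (the ODE solver keeps the loss terms, so
this approximation is itself testable); and any cell that should grow
under selection does so (establishment probability 1 — a multiplicative
`correction` hook on the estimators is provided for users who calibrate
establishment separately, default 1).

## First-event theory

With D and R deterministic exponentials and T₀ = 0, donor→recipient
conjugations form an inhomogeneous Poisson process with whole-culture
rate γ_D·D(t)·R(t)·V in a culture of V ml. The cumulative hazard is

    Λ(t) = V γ_D D₀ R₀ · t · φ((ψ_D+ψ_R) t),       φ(x) = (eˣ − 1)/x,

and the transconjugant-free probability is p₀(t) = e^(−Λ(t)). The
φ form keeps the ψ_D + ψ_R → 0 limit exact: for |x| < 10⁻⁸ φ is replaced
by its second-order series, avoiding cancellation instead of using an
epsilon offset. The first-event time t* has survival function p₀; its
mean ∫₀^∞ p₀ dt is evaluated by adaptive quadrature truncated where
p₀ < 10⁻¹², and is the recommended incubation time for the fluctuation
readout.

## Estimators

* `ldm_parametric` inverts p₀(t̃) for γ_D given known ψ_D, ψ_R.
* `ldm_endpoint` is the laboratory form: the same inversion with the
  realized rates ln(D_t̃/D₀)/t̃ and ln(R_t̃/R₀)/t̃ substituted, which
  collapses algebraically to
  f·(−ln p̂₀)·(ln D_t̃R_t̃ − ln D₀R₀)/(t̃·(D_t̃R_t̃ − D₀R₀)). The placement
  of t̃ in the denominator follows from that substitution, and the
  identity with the parametric form is enforced as a test invariant at
  10⁻¹² relative tolerance.
* `ld_mutation_rate` is the classical fluctuation-test rate; conjugation
  maps onto it via N₀ → D₀R₀, ψ_N → ψ_D + ψ_R (tested identity).
* `sim_estimate` is the end-point estimate that assumes identical growth
  and conjugation rates; its ψ defaults to the realized total-population
  rate ln(N_t̃/N₀)/t̃ and can be overridden.

The volume correction *f* (reciprocal coculture volume in ml) scales the
fluctuation-family estimates linearly; the end-point formula is written
in densities and is volume-invariant by construction. Degenerate inputs
return flagged results rather than raising: p̂₀ = 1 → a valid zero
("no_wells_turbid"), p̂₀ = 0 → invalid ("all_wells_turbid"), no net
growth or zero populations → invalid with matching codes, so sweeps can
count every outcome. Densities from replicate wells are averaged on the
linear scale before estimation.

## Stochastic engines

`gillespie_run` is an exact direct-method SSA over the five reactions
(three divisions, two conjugations) with integer counts; conjugation
propensities scale as γ·X·Y/V, with V defaulting to 1 ml so counts equal
densities. Initial counts are round(density·V); a positive density that
rounds to zero cells, or a small non-integral count, is rejected. The
time of the first D+R→D+T firing is recorded as t*. The engine refuses
configurations whose projected event count exceeds 10⁸ and points to the
hybrid engine.

`hybrid_run` exploits the model's own assumption that D and R are
effectively deterministic: it reports them from closed forms and
simulates only T, as an exact inhomogeneous birth process (immigration
γ_D D(t)R(t)/V plus per-capita ψ_T + γ_T R(t)/V) by Ogata thinning. The
majorant is piecewise constant, refreshed at each event and at least
every 0.1 hr — since all rates are nonnegative the birth rate is
nondecreasing in t for fixed T, so the window-end value is a valid bound,
and a global bound would be wasteful with R growing exponentially. By
construction t* is distributed exactly with survival function p₀, and the
engines agree on transconjugant means at scales both can afford (tested
cross-engine at 3 SE). The hybrid transconjugant count saturates at a
configurable cap (default 10⁵ per run, flagged `saturated`): in runaway
γ_T regimes the birth process is event-per-cell and otherwise unbounded.
The cap can distort late-time mean-T summaries; it does not affect t* or
any fluctuation-readout quantity.

Both inner loops consume only uniform variates from a
`numpy.random.Generator`, are JIT-compiled with numba when importable,
and fall back to pure Python with bitwise-identical streams. Ensembles
derive per-run 32-bit seeds from a master seed through
`numpy.random.SeedSequence`; every run records its seed, so any ensemble
is bitwise reproducible from (config, master_seed). Because sampling
consumes no randomness, re-running with a different sample grid replays
identical trajectories — sweeps use this to locate data-dependent readout
times on a scan grid (0.1 hr) and then replay sampled exactly at them.

## Simulation-study machinery

An ensemble (default 10,000 populations) is split into disjoint blocks of
100: each block's transconjugant-free fraction at t̃ is p̂₀, one
population chosen from the block's own seed substream supplies the
density measurements, and the end-point estimate uses the same designated
population — so 10,000 populations yield 100 estimates of each kind.
Incubation times are chosen per parameter setting and per method: the
fluctuation readout at the mean observed t* (event-free runs excluded and
counted), the end-point readout at the earliest time the mean
transconjugant count reaches 50, linearly interpolated between samples.
Incubation-time sweeps run on a 30-minute grid until the deterministic
total density reaches 10⁹ cfu/ml; a grid point is flagged excluded when
fewer than 90% of a method's estimates are finite *and* nonzero, applied
separately per method because their valid windows differ (the wording of
the rule does not separate methods; separating them is this package's
interpretation, as is reading "finite and nonzero" as both filters).
Distribution summaries use linear-interpolation quantiles (type 7) and
1.5×IQR whiskers clipped to the data range; zero estimates are retained
and counted. Group comparisons use Welch's two-sided t test on log₁₀
estimates with zeros excluded and counted (cross-checked against a
permutation test).

Default problem sizes in the test suite are scaled to what the properties
need: full 10,000-population batches for the headline recovery and
consistency checks, 200–2,000 populations for structural and
reproducibility checks, and truncated incubation grids (t̃ ≲ 6 hr) for
sweep tests, since late-time readouts in high-γ_T regimes are dominated
by the transconjugant cap discussed above.

## Plate layer

The plate CSV dialect stores plate metadata in leading `# key=value`
comment lines and one row per well (plus one row per dilution-plating
record). The fluctuation estimate from a plate uses the nonturbid
fraction of the coculture wells as p̂₀, linear-mean densities over the
density wells, and f = 1/culture volume. Controls are checked with their
expected states — donor and recipient monocultures nonturbid
(counterselection works), transconjugant monoculture turbid (selection
not too strong), end-of-assay donor+recipient mixes nonturbid (selection
suppresses further conjugation) — and a failure marks the estimate
untrusted without blocking it; a missing control class is a warning.

The synthetic plate generator emulates a 96-well assay: coculture
turbidity is Bernoulli(1 − p₀(t̃)) at the well volume (so halving the
volume raises the transconjugant-free fraction), colony counts are
Poisson around the deterministic expectations — the standard count model;
no over-dispersion from pipetting or plating inhomogeneity is modelled —
with power-of-ten dilutions chosen to land near 150 colonies, and
control wells are emitted in their expected states. What the generator
deliberately omits about real plates: establishment failure (one
transconjugant always turbids its well), growth-rate drift near
stationary phase, edge effects, and cross-well contamination. Passing
end-to-end recovery tests therefore validates the estimator arithmetic
and its sampling noise model, not those laboratory failure modes — on
real plates the control wells and the pre-assay growth checks carry that
burden.

## Numerical choices

* ODE integration: DOP853 with rtol 10⁻¹⁰ and atol 10⁻⁸ cfu/ml —
  transconjugant densities can sit many orders of magnitude below the
  other populations, and the end-point estimate needs them to ~0.1%.
* φ(x) series switchover at |x| < 10⁻⁸ (second order), used identically
  in the hazard and in both fluctuation estimators so the inversion is
  exact to machine precision.
* Quadrature for E[t*]: `scipy.integrate.quad` on [0, t_Λ=27.6] (where
  p₀ = 10⁻¹²).
* Population cap 10⁹ total count by default; runs stop there.
* Per-run seeds are uint32 words from the master `SeedSequence`.

## Known limitations

The model has no stationary phase, so 24-hour laboratory incubations
violate its constant-rate assumption — by design, the fluctuation readout
happens early (near E[t*]). The hybrid engine's deterministic D and R
ignore demographic noise, which matters only for very small inocula
(D₀·V or R₀·V of order 10 or less); use the exact engine there. The
establishment-probability correction is a hook, not a calibrated model.
Fig-style plotting (`ldmrate.plotting.sweep_boxplot`) is a convenience,
not a full graphics layer.
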